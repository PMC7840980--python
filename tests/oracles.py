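"""Independent reference implementations used only by the tests.

These stay deliberately naive — plain dynamic programming and brute
force — so that they constitute an independent check of the package's
alignment and comparison machinery rather than a re-export of it.
"""

from __future__ import annotations

MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND = 1, -2, -5, -2
STOPS = {"TAA", "TAG", "TGA"}
_COMP = str.maketrans("ACGTN", "TGCAN")


def rc(s: str) -> str:
    return s.translate(_COMP)[::-1]


def sw_score_and_identity(a: str, b: str) -> tuple[int, float]:
    """Affine-gap Smith-Waterman: best score and the identity of one
    optimal alignment (scalar DP with traceback)."""
    n, m = len(a), len(b)
    NEG = -(10 ** 9)
    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best, bi, bj = 0, 0, 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] + GAP_OPEN, E[i][j - 1] + GAP_EXTEND)
            F[i][j] = max(H[i - 1][j] + GAP_OPEN, F[i - 1][j] + GAP_EXTEND)
            sub = MATCH if a[i - 1] == b[j - 1] else MISMATCH
            H[i][j] = max(0, H[i - 1][j - 1] + sub, E[i][j], F[i][j])
            if H[i][j] > best:
                best, bi, bj = H[i][j], i, j
    if best == 0:
        return 0, 0.0
    i, j, state = bi, bj, "H"
    matches = cols = 0
    while True:
        if state == "H":
            if H[i][j] == 0:
                break
            sub = MATCH if a[i - 1] == b[j - 1] else MISMATCH
            if H[i][j] == H[i - 1][j - 1] + sub:
                matches += sub == MATCH
                cols += 1
                i -= 1
                j -= 1
            elif H[i][j] == E[i][j]:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            cols += 1
            if E[i][j] == H[i][j - 1] + GAP_OPEN:
                state = "H"
            j -= 1
        else:
            cols += 1
            if F[i][j] == H[i - 1][j] + GAP_OPEN:
                state = "H"
            i -= 1
    return best, matches / cols


def levenshtein(a: str, b: str) -> int:
    """Plain row-by-row edit distance."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i] + [0] * len(b)
        for j, cb in enumerate(b, 1):
            cur[j] = min(prev[j - 1] + (ca != cb), prev[j] + 1,
                         cur[j - 1] + 1)
        prev = cur
    return prev[-1]


def brute_common_runs(a: list, b: list) -> set[tuple[int, int, int]]:
    """All maximal common contiguous runs of two symbol lists, as
    (a_start, b_start, length) triples, by direct enumeration."""
    runs = set()
    for i in range(len(a)):
        for j in range(len(b)):
            if a[i] != b[j]:
                continue
            if i > 0 and j > 0 and a[i - 1] == b[j - 1]:
                continue  # not left-maximal
            k = 0
            while i + k < len(a) and j + k < len(b) and a[i + k] == b[j + k]:
                k += 1
            runs.add((i, j, k))
    return runs


def six_frame_orfs(seq: str, min_aa: int) -> set[tuple[int, int, str]]:
    """Brute-force ORF enumeration: (start, end, strand) on forward
    coordinates, stop codon included, leftmost ATG per stop."""
    out = set()
    n = len(seq)
    for strand, s in (("+", seq), ("-", rc(seq))):
        for frame in range(3):
            start = None
            for p in range(frame, n - 2, 3):
                codon = s[p:p + 3]
                if codon in STOPS:
                    if start is not None and (p - start) // 3 >= min_aa:
                        if strand == "+":
                            out.add((start, p + 3, "+"))
                        else:
                            out.add((n - (p + 3), n - start, "-"))
                    start = None
                elif codon == "ATG" and start is None:
                    start = p
    return out


def translate_premature(coding: str, expected_aa: int) -> bool:
    """Does translating ``coding`` hit a stop before ``expected_aa``
    codons?"""
    for k in range(0, len(coding) - 2, 3):
        if coding[k:k + 3] in STOPS:
            return k // 3 < expected_aa
    return False
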