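import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from subtelo.shp_segmenter import build_segment_library
from subtelo.synth_data import gen_patterns, gen_segment_library, gen_shp


@pytest.fixture(scope="session")
def mosaic_case():
    """A compact mosaic dataset with its truth set and the recovered
    library (built once; several tests assert different aspects)."""
    seed = 0
    exemplars, lib_truth = gen_segment_library(
        seed=seed, n_classes=6, len_range=(60, 250), n_subtype_classes=1,
        copies_range=(3, 4),
    )
    patterns = gen_patterns([r.id for r in exemplars], 4,
                            pattern_len_range=(4, 5), seed=seed)
    seqs, mosaic_truth = gen_shp(exemplars, patterns, seed=seed)
    library, annotations = build_segment_library(seqs)
    return {
        "seed": seed,
        "exemplars": exemplars,
        "library_truth": lib_truth,
        "patterns": patterns,
        "seqs": seqs,
        "mosaic_truth": mosaic_truth,
        "library": library,
        "annotations": annotations,
    }
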