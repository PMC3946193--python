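import numpy as np
import pytest

from conpromo.array_peaks import BindingPeak
from conpromo.genome_annotation import Gene, Spacer


def make_spacer(start=0, end=100, type_code="B", n_peaks=0, has_hns=False,
                left_operon=None, right_operon=None):
    """Minimal spacer with synthetic flanking genes consistent with its type."""
    strands = {"A": ("-", "+"), "B": ("+", "+"), "C": ("+", "-")}[type_code]
    left = Gene("left", max(start - 100, start - 100), start, strands[0],
                operon=left_operon)
    right = Gene("right", end, end + 100, strands[1], operon=right_operon)
    return Spacer(
        left_gene=left,
        right_gene=right,
        start=start,
        end=end,
        type_code=type_code,
        peaks=[object()] * n_peaks,
        has_hns=has_hns,
    )


def make_peak(summit, height=10.0, rel_height=1.0, n_probes=2):
    return BindingPeak(
        start=summit - 52,
        end=summit + 53,
        summit=summit,
        height=height,
        rel_height=rel_height,
        n_probes=n_probes,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
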