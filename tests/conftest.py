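import sys
from pathlib import Path

import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from varfunnel.io import CohortVariant, ObservedCall, PanelRecord, VariantKey


def _verdicts(n_deleterious: int, n_missing: int = 0):
    order = ["sift", "polyphen2", "lrt", "fathmm", "mutationtaster"]
    out = {}
    for i, p in enumerate(order):
        if i < n_deleterious:
            out[p] = "deleterious"
        elif i < n_deleterious + n_missing:
            out[p] = "missing"
        else:
            out[p] = "tolerated"
    return out


def make_variant(pos, calls, verdicts=None, gene=None, chrom="1", ref="A", alt="G"):
    return CohortVariant(
        VariantKey(chrom, pos, ref, alt),
        [ObservedCall(f"P{i:04d}", d, f) for i, (d, f) in enumerate(calls, start=1)],
        gene=gene or f"G{pos}",
        consequence="missense_variant",
        predictor_verdicts=verdicts if verdicts is not None else _verdicts(5),
    )


@pytest.fixture
def hand_traced_funnel():
    """Ten variants whose fate through every funnel stage is traced by hand.

    With default thresholds and panels CHS (n=105) / EAS (n=4327):
      v1  3 het calls, panel-absent, 5 deleterious votes      -> candidate
      v2  2 hom calls, CHS af 0.01, 2 deleterious votes       -> candidate
      v3  single call at depth 29                              -> QC drop
      v4  calls (50,0.5)+(20,0.5): one passing carrier         -> recurrence drop
      v5  2 good calls, panel afs 0.06/0.07 (both > 5%)        -> population drop
      v6  2 good calls, afs 0.06/0.01, 1 deleterious vote      -> consensus drop
      v7  2 good calls, panel-absent, 1 vote + 4 missing       -> consensus drop
      v8  2 calls at alt fraction 0.75 (off-window)            -> QC drop
      v9  4 good calls, afs 0.20/0.20                          -> population drop
      v10 2 good calls, panel-absent, 3 deleterious votes      -> candidate
    Stage counts: 10 -> 8 -> 7 -> 5 -> 3.
    """
    variants = [
        make_variant(100, [(50, 0.5)] * 3, _verdicts(5)),
        make_variant(200, [(100, 0.95)] * 2, _verdicts(2)),
        make_variant(300, [(29, 0.5)]),
        make_variant(400, [(50, 0.5), (20, 0.5)]),
        make_variant(500, [(50, 0.45)] * 2),
        make_variant(600, [(50, 0.5)] * 2, _verdicts(1)),
        make_variant(700, [(50, 0.5)] * 2, _verdicts(1, n_missing=4)),
        make_variant(800, [(50, 0.75)] * 2),
        make_variant(900, [(50, 0.5)] * 4),
        make_variant(1000, [(50, 0.55)] * 2, _verdicts(3)),
    ]
    k = lambda pos: VariantKey("1", pos, "A", "G")
    panels = {
        "CHS": {
            k(200): PanelRecord("CHS", 105, 0.01),
            k(500): PanelRecord("CHS", 105, 0.06),
            k(600): PanelRecord("CHS", 105, 0.06),
            k(900): PanelRecord("CHS", 105, 0.20),
        },
        "EAS": {
            k(500): PanelRecord("EAS", 4327, 0.07),
            k(600): PanelRecord("EAS", 4327, 0.01),
            k(900): PanelRecord("EAS", 4327, 0.20),
        },
    }
    expected_counts = [10, 8, 7, 5, 3]
    expected_candidates = {k(100), k(200), k(1000)}
    return variants, panels, expected_counts, expected_candidates
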