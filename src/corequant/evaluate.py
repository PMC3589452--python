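"""Recovery metrics: compare pipeline output against a generator ledger."""

from __future__ import annotations

import pandas as pd

from .orthology import OrthologGroupSet
from .simulate import GroundTruth
from .staging import StageAssignment


def stage_recovery(assignment: StageAssignment, truth: GroundTruth) -> bool:
    """True iff the clustering reproduces the planted day -> stage map."""
    return assignment.mapping == truth.stage_labels


def groups_recovered_exactly(groups: OrthologGroupSet, truth: GroundTruth) -> bool:
    """True iff the multi-protein groups equal the ledger's exactly."""
    found = {g for g in groups.as_set() if len(g) >= 2}
    return found == truth.multi_groups()


def call_confusion(calls: pd.DataFrame, truth: GroundTruth) -> dict[str, float]:
    """Sensitivity and false-positive rate of ΔZ calls against the ledger.

    A planted protein counts as recovered iff it is called significant on
    its planted stage pair with the planted direction (an entirely
    undetected planted protein is a miss).  The false-positive rate is the
    fraction of detected null proteins (expressed, not planted) with any
    significant call.
    """
    sig = calls[calls["significant"]]
    sig_keys = {
        (r.protein_id, r.stage_from, r.stage_to, r.direction)
        for r in sig.itertuples(index=False)
    }
    planted = truth.differential_proteins
    hits = sum(
        1
        for pid, spec in planted.items()
        if (pid, spec["stage_from"], spec["stage_to"], spec["direction"]) in sig_keys
    )
    sensitivity = hits / len(planted) if planted else float("nan")

    called_proteins = set(calls["protein_id"])
    nulls = (truth.expressed_proteins - set(planted)) & called_proteins
    flagged = nulls & set(sig["protein_id"])
    fpr = len(flagged) / len(nulls) if nulls else float("nan")
    return {
        "sensitivity": sensitivity,
        "false_positive_rate": fpr,
        "n_planted": len(planted),
        "n_null_evaluated": len(nulls),
    }
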