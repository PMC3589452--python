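"""Length-normalised log-Z quantification and ΔZ differential calls.

The quantification chain is order-fixed and enforced through the matrix
level tag::

    counts -> normalize_by_length -> log_transform -> zscore_rows
           -> impute_missing -> (stage_aggregate -> call_significance)

Row Z-scores standardise each protein across the observed samples
("conditions"), so the statistic compares a protein's temporal profile to
its own mean, not proteins to each other.  Proteins absent from one or
more samples are pushed to the matrix extremes by the presence/absence
imputation: every missing cell of a gapped row is assigned the global
minimum Z divided by ``impute_low_divisor`` and every observed cell of
that row the global maximum Z multiplied by ``impute_high_multiplier``,
producing a binary present/absent appearance in heat maps and guaranteeing
that presence/absence changes between stages are called significant.

Note the literal low-side arithmetic shrinks magnitude when the global
minimum is negative (|min/1.5| < |min|), so imputed-low cells are *not*
guaranteed to sit below all observed values; the rule is applied exactly
as stated and this behaviour is covered by a dedicated test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .catalog import ProteinCatalog
from .matrix import AbundanceMatrix

STAGE_PAIR_COLUMNS = (
    "protein_id",
    "stage_from",
    "stage_to",
    "delta_z",
    "direction",
    "significant",
)


@dataclass
class ZPolicy:
    """Settings for the Z-score chain and the ΔZ significance rule.

    sign
        ``"standard"``: z = (x - mean)/sd, so higher abundance gives higher
        Z.  ``"literal"``: z = (mean - x)/sd, the inverted form implied by
        reading the standardisation recipe word for word; provided as a
        switch, not the default, because abundance-increase language and
        heat-map orientation assume the standard sign.
    sd_mode
        ``"sample"`` (n-1 denominator, default) or ``"population"`` (n).
    """

    log_base: float = 10.0
    sd_mode: str = "sample"
    sign: str = "standard"
    impute_low_divisor: float = 1.5
    impute_high_multiplier: float = 1.5
    delta_z_threshold: float = 2.0

    def __post_init__(self) -> None:
        if self.log_base <= 1:
            raise ValueError("log_base must be > 1")
        if self.sd_mode not in ("sample", "population"):
            raise ValueError("sd_mode must be 'sample' or 'population'")
        if self.sign not in ("standard", "literal"):
            raise ValueError("sign must be 'standard' or 'literal'")
        if self.impute_low_divisor <= 0 or self.impute_high_multiplier <= 0:
            raise ValueError("imputation factors must be positive")
        if self.delta_z_threshold <= 0:
            raise ValueError("delta_z_threshold must be positive")


# ---------------------------------------------------------------------------
# transforms


def normalize_by_length(m: AbundanceMatrix, catalog: ProteinCatalog) -> AbundanceMatrix:
    """Divide each protein's spectral counts by its amino-acid length."""
    m.require_level("counts")
    lengths = catalog.lengths().reindex(m.protein_ids)
    if lengths.isna().any():
        bad = list(m.protein_ids[lengths.isna()])
        raise ValueError(f"proteins without catalog lengths: {bad[:5]}")
    if (lengths <= 0).any():
        raise ValueError("protein lengths must be positive")
    values = m.values.div(lengths, axis=0)
    return m.with_values(values, "normalized")


def log_transform(m: AbundanceMatrix, policy: ZPolicy | None = None) -> AbundanceMatrix:
    policy = policy or ZPolicy()
    m.require_level("normalized")
    present = m.present_values()
    if present.size and np.any(present <= 0):
        raise ValueError(
            "log transform requires positive values; a zero count should "
            "have been recorded as missing upstream"
        )
    values = np.log(m.values) / np.log(policy.log_base)
    return m.with_values(values, "log")


def zscore_rows(m: AbundanceMatrix, policy: ZPolicy | None = None) -> AbundanceMatrix:
    """Standardise each row over its observed samples.

    Rows with fewer than two observed values have no defined standard
    deviation; their observed cells are set to NaN and resolved by the
    imputation step (such rows necessarily contain missing cells).
    Constant rows (sd = 0) map to all-zero Z.
    """
    policy = policy or ZPolicy()
    m.require_level("log")
    if m.shape[1] < 2:
        raise ValueError("row Z-scores require at least two samples")
    arr = m.values.to_numpy(copy=True)
    mask = m.missing_mask.to_numpy()
    arr[mask] = np.nan
    n_present = (~mask).sum(axis=1)
    ddof = 1 if policy.sd_mode == "sample" else 0
    out = np.full_like(arr, np.nan)
    ok = n_present >= 2
    if ok.any():
        mean = np.nanmean(arr[ok], axis=1, keepdims=True)
        sd = np.nanstd(arr[ok], axis=1, ddof=ddof, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = (arr[ok] - mean) / sd
        z[np.broadcast_to(sd == 0, z.shape)] = 0.0
        if policy.sign == "literal":
            z = -z
        out[ok] = z
    out[mask] = np.nan
    values = pd.DataFrame(out, index=m.protein_ids, columns=m.sample_ids)
    return m.with_values(values, "zscore")


def impute_missing(m: AbundanceMatrix, policy: ZPolicy | None = None) -> AbundanceMatrix:
    """Presence/absence imputation at the global matrix extremes.

    The global minimum and maximum Z over observed cells are computed once,
    before any assignment.  For every row containing at least one missing
    cell, missing cells receive ``min/impute_low_divisor`` and the row's
    observed cells receive ``max*impute_high_multiplier``; fully observed
    rows pass through unchanged.
    """
    policy = policy or ZPolicy()
    m.require_level("zscore")
    arr = m.values.to_numpy(copy=True)
    mask = m.missing_mask.to_numpy()
    if mask.all():
        raise ValueError("cannot impute an all-missing matrix")
    observed = arr[~mask]
    observed = observed[~np.isnan(observed)]
    if observed.size == 0:
        raise ValueError("no defined Z-scores to take matrix extremes from")
    low = observed.min() / policy.impute_low_divisor
    high = observed.max() * policy.impute_high_multiplier
    gapped = mask.any(axis=1)
    arr[gapped] = np.where(mask[gapped], low, high)
    values = pd.DataFrame(arr, index=m.protein_ids, columns=m.sample_ids)
    return m.with_values(values, "zscore_imputed")


def quantify(
    counts: AbundanceMatrix,
    catalog: ProteinCatalog,
    policy: ZPolicy | None = None,
) -> AbundanceMatrix:
    """Run the full chain counts -> imputed Z in the fixed order."""
    policy = policy or ZPolicy()
    return impute_missing(
        zscore_rows(log_transform(normalize_by_length(counts, catalog), policy), policy),
        policy,
    )


# ---------------------------------------------------------------------------
# stage aggregation and significance calls


def stage_aggregate(
    m: AbundanceMatrix,
    stage_of_sample: dict[str, str],
    stage_order: list[str],
) -> pd.DataFrame:
    """Mean of each protein's values over each stage's samples.

    ``stage_of_sample`` maps sample id to stage label; every sample must be
    assigned and every stage in ``stage_order`` must be non-empty.
    """
    unassigned = [s for s in m.sample_ids if s not in stage_of_sample]
    if unassigned:
        raise ValueError(f"samples without a stage: {unassigned}")
    out = {}
    for stage in stage_order:
        cols = [s for s in m.sample_ids if stage_of_sample[s] == stage]
        if not cols:
            raise ValueError(f"stage {stage!r} has no samples")
        out[stage] = m.values[cols].mean(axis=1)
    return pd.DataFrame(out, index=m.protein_ids)[stage_order]


def call_significance(
    stage_matrix: pd.DataFrame,
    policy: ZPolicy | None = None,
    heuristic_p: bool = False,
) -> pd.DataFrame:
    """ΔZ calls between ordered adjacent stage pairs.

    For each adjacent pair (from, to) in the stage matrix column order and
    each protein: ``delta_z = z(to) - z(from)``; the call is significant iff
    ``|delta_z| >= delta_z_threshold`` (boundary inclusive) with the
    direction given by the sign.

    ``heuristic_p`` adds a two-sided normal-tail p-value for
    ``delta_z / sqrt(2)``.  This is a descriptive convenience only — the ΔZ
    rule itself is the inferential criterion — and is labelled accordingly.
    """
    policy = policy or ZPolicy()
    stages = list(stage_matrix.columns)
    if len(stages) < 2:
        raise ValueError("significance calls require at least two stages")
    frames = []
    for s_from, s_to in zip(stages[:-1], stages[1:]):
        delta = stage_matrix[s_to] - stage_matrix[s_from]
        frame = pd.DataFrame(
            {
                "protein_id": stage_matrix.index,
                "stage_from": s_from,
                "stage_to": s_to,
                "delta_z": delta.to_numpy(),
            }
        )
        frames.append(frame)
    calls = pd.concat(frames, ignore_index=True)
    calls["direction"] = np.where(calls["delta_z"] >= 0, "increased", "decreased")
    calls["significant"] = np.abs(calls["delta_z"]) >= policy.delta_z_threshold
    if heuristic_p:
        calls["p_heuristic"] = 2 * stats.norm.sf(np.abs(calls["delta_z"]) / np.sqrt(2))
    return calls


# ---------------------------------------------------------------------------
# sklearn-style transformers


class LengthNormalizer(BaseEstimator, TransformerMixin):
    def __init__(self, catalog: ProteinCatalog | None = None) -> None:
        self.catalog = catalog

    def fit(self, X: AbundanceMatrix, y=None):
        if self.catalog is None:
            raise ValueError("LengthNormalizer requires a catalog")
        return self

    def transform(self, X: AbundanceMatrix) -> AbundanceMatrix:
        if self.catalog is None:
            raise ValueError("LengthNormalizer requires a catalog")
        return normalize_by_length(X, self.catalog)


class LogTransformer(BaseEstimator, TransformerMixin):
    def __init__(self, log_base: float = 10.0) -> None:
        self.log_base = log_base

    def fit(self, X: AbundanceMatrix, y=None):
        return self

    def transform(self, X: AbundanceMatrix) -> AbundanceMatrix:
        return log_transform(X, ZPolicy(log_base=self.log_base))


class RowZScorer(BaseEstimator, TransformerMixin):
    def __init__(self, sd_mode: str = "sample", sign: str = "standard") -> None:
        self.sd_mode = sd_mode
        self.sign = sign

    def fit(self, X: AbundanceMatrix, y=None):
        return self

    def transform(self, X: AbundanceMatrix) -> AbundanceMatrix:
        return zscore_rows(X, ZPolicy(sd_mode=self.sd_mode, sign=self.sign))


class ExtremeValueImputer(BaseEstimator, TransformerMixin):
    """Presence/absence imputation at the global matrix extremes."""

    def __init__(self, low_divisor: float = 1.5, high_multiplier: float = 1.5) -> None:
        self.low_divisor = low_divisor
        self.high_multiplier = high_multiplier

    def fit(self, X: AbundanceMatrix, y=None):
        return self

    def transform(self, X: AbundanceMatrix) -> AbundanceMatrix:
        return impute_missing(
            X,
            ZPolicy(
                impute_low_divisor=self.low_divisor,
                impute_high_multiplier=self.high_multiplier,
            ),
        )
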