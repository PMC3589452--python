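"""Peptide-spectrum match filtering and protein-level spectral-count roll-up.

Peptide identifications from a database search are filtered with
charge-dependent cross-correlation (Xcorr) thresholds and a spectral
probability cutoff, low-evidence peptides (a single spectral count in the
whole experiment) are discarded, and surviving peptides are summed into a
protein x sample spectral-count matrix.  Cells with no surviving peptide
are *missing*, not zero: absence of identification is handled downstream
by the presence/absence imputation, never conflated with an observed zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .catalog import ProteinCatalog
from .matrix import AbundanceMatrix

PSM_COLUMNS = ("peptide", "protein_id", "charge", "xcorr", "msgf", "sample_id", "count")

#: Conventional conservative SEQUEST thresholds by precursor charge state.
DEFAULT_XCORR_MIN = {1: 1.9, 2: 2.2, 3: 3.5}


def _validate_psms(records: pd.DataFrame) -> None:
    missing = set(PSM_COLUMNS) - set(records.columns)
    if missing:
        raise ValueError(f"PSM table missing columns: {sorted(missing)}")
    if len(records):
        if (records["count"] < 0).any():
            raise ValueError("spectral counts must be non-negative")
        msgf = records["msgf"]
        if ((msgf <= 0) | (msgf > 1)).any():
            raise ValueError("msgf spectral probabilities must lie in (0, 1]")
        if (records["charge"] < 1).any():
            raise ValueError("charge states must be >= 1")


@dataclass
class FilterPolicy:
    """Peptide-level filter settings.

    All thresholds are boundary-inclusive: a peptide passes with
    ``xcorr >= xcorr_min_by_charge[charge]`` and ``msgf <= msgf_max``.

    ``charge_overflow`` controls charges above the highest key in
    ``xcorr_min_by_charge``: ``"clamp"`` applies the highest-charge
    threshold, ``"error"`` rejects the row.

    ``count_scope`` controls the single-spectral-count discard: under
    ``"global"`` (default) a peptide's counts are summed over all samples
    before the test, so a peptide seen once in each of two samples is kept;
    under ``"per_sample"`` the test is applied within each sample.
    """

    xcorr_min_by_charge: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_XCORR_MIN)
    )
    charge_overflow: str = "clamp"
    msgf_max: float = 1e-10
    min_total_count: int = 2
    count_scope: str = "global"

    def __post_init__(self) -> None:
        if any(t <= 0 for t in self.xcorr_min_by_charge.values()):
            raise ValueError("Xcorr thresholds must be positive")
        if not (0.0 < self.msgf_max < 1.0):
            raise ValueError("msgf_max must lie in (0, 1)")
        if self.charge_overflow not in ("clamp", "error"):
            raise ValueError("charge_overflow must be 'clamp' or 'error'")
        if self.count_scope not in ("global", "per_sample"):
            raise ValueError("count_scope must be 'global' or 'per_sample'")


def filter_psms(records: pd.DataFrame, policy: FilterPolicy | None = None) -> pd.DataFrame:
    """Keep rows passing the charge-specific Xcorr and the msgf cutoffs.

    Row order is preserved.  Unknown charges raise unless the policy's
    overflow rule clamps them to the highest configured threshold.
    """
    policy = policy or FilterPolicy()
    _validate_psms(records)
    if not len(records):
        return records.copy()
    max_charge = max(policy.xcorr_min_by_charge)
    charges = records["charge"].to_numpy()
    unknown = ~np.isin(charges, list(policy.xcorr_min_by_charge))
    if unknown.any():
        if policy.charge_overflow == "error" or (charges[unknown] < max_charge).any():
            bad = records.index[unknown][0]
            raise ValueError(
                f"no Xcorr threshold for charge {records.loc[bad, 'charge']} "
                f"(row {bad}) and no applicable overflow rule"
            )
    thresholds = np.array(
        [policy.xcorr_min_by_charge.get(min(c, max_charge)) for c in charges]
    )
    keep = (records["xcorr"].to_numpy() >= thresholds) & (
        records["msgf"].to_numpy() <= policy.msgf_max
    )
    return records.loc[keep].copy()


def drop_single_count_peptides(
    records: pd.DataFrame, policy: FilterPolicy | None = None
) -> pd.DataFrame:
    """Discard peptides whose total spectral count falls below the minimum.

    With the default global scope, counts are summed across all samples
    (shared-peptide rows duplicated across proteins are de-duplicated per
    (peptide, sample) first so they are not double counted); peptides with
    a total below ``min_total_count`` (default 2, i.e. single-count
    peptides) are removed everywhere.  Under per-sample scope the test is
    applied within each sample independently.
    """
    policy = policy or FilterPolicy()
    _validate_psms(records)
    if not len(records):
        return records.copy()
    unique = records.drop_duplicates(subset=["peptide", "sample_id"])
    if policy.count_scope == "global":
        totals = unique.groupby("peptide")["count"].sum()
        keep_peptides = set(totals.index[totals >= policy.min_total_count])
        keep = records["peptide"].isin(keep_peptides)
    else:
        totals = unique.groupby(["peptide", "sample_id"])["count"].sum()
        ok = set(totals.index[totals >= policy.min_total_count])
        keys = list(zip(records["peptide"], records["sample_id"]))
        keep = pd.Series([k in ok for k in keys], index=records.index)
    return records.loc[keep].copy()


def rollup(
    records: pd.DataFrame,
    catalog: ProteinCatalog,
    sample_ids: list[str] | None = None,
    shared_peptides: str = "credit_all",
) -> AbundanceMatrix:
    """Sum surviving peptide counts into a protein x sample counts matrix.

    A cell is the sum of counts of the protein's peptides in that sample;
    (protein, sample) combinations with no surviving peptide are marked
    missing.  Peptides mapping to more than one protein are credited once
    to every mapped protein (``shared_peptides="credit_all"``) or removed
    entirely (``"drop"``).  Rows cover the proteins with at least one
    surviving peptide; column order follows ``sample_ids`` when given
    (allowing empty samples to appear as all-missing columns).
    """
    if shared_peptides not in ("credit_all", "drop"):
        raise ValueError("shared_peptides must be 'credit_all' or 'drop'")
    _validate_psms(records)
    known = set(catalog.protein_ids)
    offenders = sorted(set(records["protein_id"]) - known)
    if offenders:
        raise ValueError(f"protein ids absent from catalog: {offenders}")
    work = records
    if shared_peptides == "drop" and len(records):
        n_proteins = records.groupby("peptide")["protein_id"].nunique()
        shared = set(n_proteins.index[n_proteins > 1])
        work = records.loc[~records["peptide"].isin(shared)]
    if len(work):
        cells = work.groupby(["protein_id", "sample_id"])["count"].sum()
        values = cells.unstack("sample_id")
    else:
        values = pd.DataFrame(dtype=float)
    if sample_ids is not None:
        values = values.reindex(columns=sample_ids)
    values = values.sort_index()
    return AbundanceMatrix(values, level="counts")


class PSMFilter(BaseEstimator, TransformerMixin):
    """Stateless transformer applying the score filters and count discard.

    Composes :func:`filter_psms` and :func:`drop_single_count_peptides`,
    exposed as an estimator so the identification step slots into sklearn
    pipelines alongside the matrix transformers.
    """

    def __init__(
        self,
        xcorr_min_by_charge: dict[int, float] | None = None,
        charge_overflow: str = "clamp",
        msgf_max: float = 1e-10,
        min_total_count: int = 2,
        count_scope: str = "global",
    ) -> None:
        self.xcorr_min_by_charge = xcorr_min_by_charge
        self.charge_overflow = charge_overflow
        self.msgf_max = msgf_max
        self.min_total_count = min_total_count
        self.count_scope = count_scope

    def _policy(self) -> FilterPolicy:
        return FilterPolicy(
            xcorr_min_by_charge=dict(self.xcorr_min_by_charge or DEFAULT_XCORR_MIN),
            charge_overflow=self.charge_overflow,
            msgf_max=self.msgf_max,
            min_total_count=self.min_total_count,
            count_scope=self.count_scope,
        )

    def fit(self, X: pd.DataFrame, y=None) -> "PSMFilter":
        _validate_psms(X)
        self.n_input_rows_ = len(X)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        policy = self._policy()
        return drop_single_count_peptides(filter_psms(X, policy), policy)


class SpectralCountRollup(BaseEstimator, TransformerMixin):
    """Transformer form of :func:`rollup`: PSM table -> counts matrix."""

    def __init__(
        self,
        catalog: ProteinCatalog | None = None,
        sample_ids: list[str] | None = None,
        shared_peptides: str = "credit_all",
    ) -> None:
        self.catalog = catalog
        self.sample_ids = sample_ids
        self.shared_peptides = shared_peptides

    def fit(self, X: pd.DataFrame, y=None) -> "SpectralCountRollup":
        if self.catalog is None:
            raise ValueError("SpectralCountRollup requires a catalog")
        return self

    def transform(self, X: pd.DataFrame) -> AbundanceMatrix:
        if self.catalog is None:
            raise ValueError("SpectralCountRollup requires a catalog")
        return rollup(X, self.catalog, self.sample_ids, self.shared_peptides)
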