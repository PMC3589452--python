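"""COG-category summaries of differential calls and pathway export matrices.

Two percentage conventions are computed side by side, because both are in
common use when reporting stage-to-stage shifts: counts of significantly
changed proteins per category expressed (i) as a percentage of *all*
proteins detected across the experiment, and (ii) as a percentage of the
detected proteins *in that category* (the "X% of detected ribosomal
proteins increased" convention).  Proteins without a COG assignment are
binned under the pseudo-category ``-`` so that counts conserve.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd

from .catalog import UNANNOTATED
from .matrix import AbundanceMatrix
from .orthology import DetectionSet
from .quantification import stage_aggregate

SUMMARY_COLUMNS = (
    "stage_from",
    "stage_to",
    "cog",
    "n_detected_category",
    "n_increased",
    "n_decreased",
    "pct_increased_of_total",
    "pct_decreased_of_total",
    "pct_increased_of_category",
    "pct_decreased_of_category",
)


def summarize_shifts(
    calls: pd.DataFrame,
    cogs: Mapping[str, str],
    detection: DetectionSet,
) -> pd.DataFrame:
    """Per stage pair and COG category: significant-shift counts and
    percentages under the of-all-detected and within-category conventions.

    ``calls`` is the significance table from
    :func:`corequant.quantification.call_significance`; ``cogs`` maps
    protein id to its primary category letter (missing ids fall into
    ``-``).  The denominator for the "of total" view is the number of
    proteins detected anywhere in the experiment; for the within-category
    view it is the number of detected proteins carrying that category.
    """
    detected = detection.detected_anywhere
    n_total = len(detected)

    def category(pid: str) -> str:
        c = cogs.get(pid, UNANNOTATED)
        return c if isinstance(c, str) and c.strip() else UNANNOTATED

    cat_counts: dict[str, int] = {}
    for pid in detected:
        cat_counts[category(pid)] = cat_counts.get(category(pid), 0) + 1

    rows = []
    pair_order = calls[["stage_from", "stage_to"]].drop_duplicates().itertuples(index=False)
    for s_from, s_to in pair_order:
        sub = calls[
            (calls["stage_from"] == s_from)
            & (calls["stage_to"] == s_to)
            & calls["significant"]
        ]
        by_cat: dict[str, dict[str, int]] = {}
        for row in sub.itertuples(index=False):
            cat = category(row.protein_id)
            slot = by_cat.setdefault(cat, {"increased": 0, "decreased": 0})
            slot[row.direction] += 1
        categories = sorted(set(cat_counts) | set(by_cat))
        for cat in categories:
            inc = by_cat.get(cat, {}).get("increased", 0)
            dec = by_cat.get(cat, {}).get("decreased", 0)
            n_cat = cat_counts.get(cat, 0)
            rows.append(
                {
                    "stage_from": s_from,
                    "stage_to": s_to,
                    "cog": cat,
                    "n_detected_category": n_cat,
                    "n_increased": inc,
                    "n_decreased": dec,
                    "pct_increased_of_total": 100.0 * inc / n_total if n_total else 0.0,
                    "pct_decreased_of_total": 100.0 * dec / n_total if n_total else 0.0,
                    "pct_increased_of_category": 100.0 * inc / n_cat if n_cat else 0.0,
                    "pct_decreased_of_category": 100.0 * dec / n_cat if n_cat else 0.0,
                }
            )
    return pd.DataFrame(rows, columns=list(SUMMARY_COLUMNS))


def pathway_matrix(
    log_matrix: AbundanceMatrix,
    z_matrix: AbundanceMatrix,
    protein_list: Iterable[str],
    stage_of_sample: dict[str, str],
    stage_order: list[str],
    core_proteins: set[str] | None = None,
) -> pd.DataFrame:
    """Stage-aggregated export matrix for a named protein list.

    Extracts the listed proteins in the given order at both the log and
    Z levels, averaged per stage, ready for heat-map rendering.  The
    ``core`` column flags proteins belonging to the all-panel core set
    (rendered bold in heat maps).  Unknown protein ids raise, listing the
    offenders; an empty list yields an empty frame.
    """
    proteins = list(protein_list)
    if not proteins:
        cols = pd.MultiIndex.from_product([("log", "zscore"), stage_order])
        out = pd.DataFrame(columns=cols)
        out["core"] = pd.Series(dtype=bool)
        return out
    log_matrix.require_level("log")
    z_matrix.require_level("zscore", "zscore_imputed")
    unknown = [p for p in proteins if p not in log_matrix.protein_ids]
    unknown += [
        p for p in proteins if p not in z_matrix.protein_ids and p not in unknown
    ]
    if unknown:
        raise ValueError(f"proteins not in matrix: {unknown}")
    log_stage = stage_aggregate(log_matrix, stage_of_sample, stage_order).loc[proteins]
    z_stage = stage_aggregate(z_matrix, stage_of_sample, stage_order).loc[proteins]
    out = pd.concat({"log": log_stage, "zscore": z_stage}, axis=1)
    core = core_proteins or set()
    out["core"] = [p in core for p in proteins]
    return out


def plot_pathway_heatmap(matrix: pd.DataFrame, path: str, level: str = "zscore") -> None:
    """Render a pathway export matrix as a PNG heat map.

    Core proteins (``core`` column) get bold row labels.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = matrix[level]
    fig, ax = plt.subplots(
        figsize=(1.2 * data.shape[1] + 3, 0.35 * max(len(data), 4) + 1.5)
    )
    im = ax.imshow(data.to_numpy(), aspect="auto", cmap="RdBu_r")
    ax.set_xticks(range(data.shape[1]), data.columns)
    ax.set_yticks(range(len(data)), data.index)
    if "core" in matrix.columns:
        for label, is_core in zip(ax.get_yticklabels(), matrix["core"]):
            if is_core:
                label.set_fontweight("bold")
    fig.colorbar(im, ax=ax, label=level)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
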