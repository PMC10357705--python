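"""Stratification of dark-gene proportions by category and association strength.

Candidate genes (e.g. SFARI-scored autism genes) are partitioned into
q-value bins crossed with their confidence category, and the proportion of
dark genes is reported per cell. With the default breakpoints (0.1, 0.3)
the bins follow the phrasing "less than 0.1; 0.1 to 0.3, greater than 0.3":
[0, 0.1), [0.1, 0.3], (0.3, 1]. Genes without a q-value go to an
"unscored" bin; genes without a dark report go to an "unannotated" row.
"""

from __future__ import annotations

import logging
from typing import Dict, Optional, Sequence, Tuple

import pandas as pd
from scipy.stats import chi2_contingency

from .models import DarkCoverageReport, GeneRecord

logger = logging.getLogger(__name__)

__all__ = ["assign_bin", "stratify", "stratification_chi2"]

UNSCORED = "unscored"
UNCATEGORIZED = "uncategorized"


def bin_labels(bins: Sequence[float]) -> Tuple[str, ...]:
    labels = [f"<{bins[0]:g}"]
    for lo, hi in zip(bins, bins[1:]):
        labels.append(f"{lo:g}-{hi:g}")
    labels.append(f">{bins[-1]:g}")
    return tuple(labels)


def assign_bin(q: Optional[float], bins: Sequence[float]) -> str:
    """Bin a q-value.

    First bin is right-open ([0, b1)); the following bins are closed on the
    left edge and closed on the right edge of the last breakpoint
    ([b1, b2]); everything above the final breakpoint is the open top bin.
    """
    labels = bin_labels(bins)
    if q is None:
        return UNSCORED
    if q < bins[0]:
        return labels[0]
    for i, (lo, hi) in enumerate(zip(bins, bins[1:])):
        if lo <= q <= hi:
            return labels[i + 1]
    return labels[-1]


def stratify(
    records: Sequence[GeneRecord],
    reports: Dict[str, DarkCoverageReport],
    bins: Sequence[float] = (0.1, 0.3),
    dark_definition: str = "body",
) -> pd.DataFrame:
    """Per-(category, q-bin) counts and dark-gene proportions.

    ``dark_definition`` selects which report flag marks a gene dark:
    ``body`` (any dark gene body, the default) or ``cds`` (any dark CDS).
    Every record lands in exactly one cell; the output is sorted and
    independent of record order.
    """
    if dark_definition not in ("body", "cds"):
        raise ValueError(f"dark_definition must be 'body' or 'cds', got {dark_definition!r}")
    b = [float(x) for x in bins]
    if not b or any(x2 <= x1 for x1, x2 in zip(b, b[1:])) or b[0] <= 0 or b[-1] >= 1:
        raise ValueError("bins must be strictly increasing within (0, 1)")

    counts: Dict[Tuple[str, str], Dict[str, int]] = {}
    n_unannotated = 0
    for rec in records:
        category = rec.category if rec.category is not None else UNCATEGORIZED
        report = reports.get(rec.gene_id)
        if report is None:
            qbin = "unannotated"
            dark = False
            n_unannotated += 1
        else:
            qbin = assign_bin(rec.q_value, b)
            dark = (
                report.any_dark_body
                if dark_definition == "body"
                else report.any_dark_cds
            )
        cell = counts.setdefault((category, qbin), {"n_genes": 0, "n_dark": 0})
        cell["n_genes"] += 1
        cell["n_dark"] += int(dark)
    if n_unannotated:
        logger.warning(
            "%d gene records had no dark report; counted as 'unannotated'",
            n_unannotated,
        )

    order = {lab: i for i, lab in enumerate(bin_labels(b) + (UNSCORED, "unannotated"))}
    rows = [
        {
            "category": cat,
            "q_bin": qbin,
            "n_genes": c["n_genes"],
            "n_dark": c["n_dark"],
            "proportion_dark": c["n_dark"] / c["n_genes"] if c["n_genes"] else float("nan"),
        }
        for (cat, qbin), c in counts.items()
    ]
    df = pd.DataFrame(
        rows, columns=["category", "q_bin", "n_genes", "n_dark", "proportion_dark"]
    )
    if df.empty:
        return df
    df["_bin_order"] = df["q_bin"].map(order)
    df = df.sort_values(["category", "_bin_order"], kind="mergesort").drop(
        columns="_bin_order"
    )
    return df.reset_index(drop=True)


def stratification_chi2(table: pd.DataFrame) -> Tuple[float, float]:
    """Optional chi-square test of dark-count homogeneity across cells.

    Off by default in the pipeline; the headline output is the proportion
    table itself.
    """
    observed = table[["n_dark"]].copy()
    observed["n_not_dark"] = table["n_genes"] - table["n_dark"]
    observed = observed[(observed.sum(axis=1) > 0)]
    stat, p, _, _ = chi2_contingency(observed.to_numpy())
    return float(stat), float(p)
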