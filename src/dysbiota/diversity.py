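"""Companion community measures: α-diversity, F/B ratio, abundance filter.

These accompany the pathogenic-content statistic the way they are routinely
used in gut-microbiome studies: Shannon and inverse Simpson indices describe
within-sample variety, the Firmicutes/Bacteroidetes phylum ratio proxies the
inflammatory/dysbiotic state, and a low-abundance filter removes noisy genera
before differential analysis.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skbio.diversity import alpha as _skbio_alpha


def _proportions(counts) -> np.ndarray:
    arr = np.asarray(counts, dtype=float)
    if arr.ndim != 1:
        raise ValueError("counts must be a 1-D abundance vector")
    if np.any(arr < 0):
        raise ValueError("counts must be nonnegative")
    total = arr.sum()
    if total <= 0:
        raise ValueError("all-zero abundance vector has undefined diversity")
    return arr / total


def shannon(counts, base: float | None = None) -> float:
    """Shannon diversity H = −Σ p_i log p_i of one sample's abundances.

    Natural log (nats) by default, the conventional ecology definition;
    pass ``base`` for bits (2) or dits (10). Zero-count taxa are skipped.
    """
    _proportions(counts)  # validation (skbio accepts all-zero vectors)
    arr = np.asarray(counts, dtype=float)
    return float(_skbio_alpha.shannon(arr[arr > 0], base=base))


def inverse_simpson(counts) -> float:
    """Inverse Simpson index 1/Σ p_i², the effective number of taxa."""
    _proportions(counts)
    return float(_skbio_alpha.inv_simpson(np.asarray(counts, dtype=float)))


def alpha_diversity_table(matrix: pd.DataFrame) -> pd.DataFrame:
    """Shannon (nats) and inverse Simpson per sample of a samples × taxa matrix."""
    _check_count_matrix(matrix)
    return pd.DataFrame(
        {
            "shannon": [shannon(matrix.loc[s]) for s in matrix.index],
            "inverse_simpson": [inverse_simpson(matrix.loc[s]) for s in matrix.index],
        },
        index=matrix.index,
    )


def fb_ratio(
    phylum_counts: pd.DataFrame,
    groups: Mapping[str, str] | pd.Series | None = None,
    firmicutes: str = "Firmicutes",
    bacteroidetes: str = "Bacteroidetes",
) -> tuple[pd.Series, pd.DataFrame | None]:
    """Per-sample Firmicutes/Bacteroidetes ratio, with per-arm mean ± s.e.m.

    Parameters
    ----------
    phylum_counts
        Samples × phyla abundance matrix containing both phylum columns.
    groups
        Optional sample -> arm labels; when given, the second return value
        summarizes each arm as mean ± standard error of the mean.

    Samples with zero Bacteroidetes have an undefined ratio and are excluded
    with a warning.
    """
    for col in (firmicutes, bacteroidetes):
        if col not in phylum_counts.columns:
            raise ValueError(f"phylum column {col!r} missing")
    f = phylum_counts[firmicutes].astype(float)
    b = phylum_counts[bacteroidetes].astype(float)
    defined = b > 0
    if not defined.all():
        excluded = list(phylum_counts.index[~defined])
        warnings.warn(
            f"F/B ratio undefined (zero Bacteroidetes) for samples "
            f"{excluded}; excluded"
        )
    ratios = (f[defined] / b[defined]).rename("fb_ratio")

    summary = None
    if groups is not None:
        grp = pd.Series(groups).reindex(ratios.index)
        agg = ratios.groupby(grp).agg(["mean", "sem", "count"])
        summary = agg.rename(columns={"count": "n"})
    return ratios, summary


def _check_count_matrix(matrix: pd.DataFrame) -> None:
    if (matrix.to_numpy(dtype=float) < 0).any():
        raise ValueError("count matrix has negative entries")


def filter_low_abundance(
    matrix: pd.DataFrame,
    groups: Mapping[str, str] | pd.Series | None = None,
    max_zero_samples: int = 1,
    min_group_sum: float = 5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop low-abundance genera from a samples × genera count matrix.

    Within each group (all samples form one group when *groups* is None), a
    genus is removed if it has a zero count in more than ``max_zero_samples``
    samples, or if its summed abundance over the group's samples is below
    ``min_group_sum``. A genus failing the rule in any group is dropped
    everywhere, and the filter is idempotent.

    Returns the filtered matrix and a removal report with one row per
    (genus, group) violation.
    """
    _check_count_matrix(matrix)
    if groups is None:
        grp = pd.Series("all", index=matrix.index)
    else:
        grp = pd.Series(groups).reindex(matrix.index)
        if grp.isna().any():
            raise ValueError(
                f"samples without group label: {list(matrix.index[grp.isna()])}"
            )

    drop: set[str] = set()
    report_rows = []
    for group_label, sub in matrix.groupby(grp):
        zeros = (sub == 0).sum(axis=0)
        sums = sub.sum(axis=0)
        for genus in matrix.columns:
            reasons = []
            if zeros[genus] > max_zero_samples:
                reasons.append(f"{int(zeros[genus])} zero-count samples")
            if sums[genus] < min_group_sum:
                reasons.append(f"group sum {sums[genus]:g} < {min_group_sum:g}")
            if reasons:
                drop.add(genus)
                report_rows.append(
                    {
                        "genus": genus,
                        "group": group_label,
                        "reason": "; ".join(reasons),
                    }
                )
    kept = matrix.drop(columns=sorted(drop))
    report = pd.DataFrame(report_rows, columns=["genus", "group", "reason"])
    return kept, report


def collapse_otus_to_genus(
    matrix: pd.DataFrame,
    genus_of_otu: Mapping[str, str],
    higher_order_prefix: str = "unclassified:",
) -> tuple[pd.DataFrame, list[str]]:
    """Sum OTU columns into genus columns.

    OTUs lacking a genus-level name map to ``unclassified:<nearest rank>``
    columns; those column names are returned separately so downstream
    annotation can exclude them (taxa resolvable only to higher-order ranks
    cannot be annotated harmful/harmless).
    """
    missing = [o for o in matrix.columns if o not in genus_of_otu]
    if missing:
        raise ValueError(f"OTUs without taxonomy mapping: {missing[:10]}")
    collapsed = matrix.T.groupby(
        [genus_of_otu[o] for o in matrix.columns]
    ).sum().T
    flagged = [
        c for c in collapsed.columns if str(c).startswith(higher_order_prefix)
    ]
    return collapsed, flagged
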