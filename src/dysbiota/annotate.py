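"""Annotate differential genera as harmful, harmless, or discarded.

A genus can shelter both harmful and harmless species, so when the species
actually observed in the dataset are known (species mode), annotation is
refined: a pathogen-listed genus is *harmful* only if at least one of its
observed species is a listed pathogen; it is *harmless* if species were
observed but none is listed; it is *discarded* when none of its species was
observed, since its harmfulness cannot be decided. A genus entirely absent
from the pathogen table is annotated *harmless* — the conservative default
for taxa never explicitly disease-associated (``strict_discard=True`` instead
discards every genus without observed species, listed or not). Without an
observed-species map (genus-only mode), annotation falls back to table
membership of the genus and nothing is discarded.
"""

from __future__ import annotations

import logging
import math
import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .pathogens import PathogenTable

logger = logging.getLogger(__name__)

HARMLESS = "harmless"
HARMFUL = "harmful"
DISCARDED = "discarded"
LABELS = (HARMLESS, HARMFUL, DISCARDED)


@dataclass(frozen=True)
class DifferentialGenus:
    """A signed genus abundance variation between two conditions.

    ``delta`` is the genus abundance in condition 1 minus its abundance in
    the baseline condition 2, in the user's abundance units (reads or
    normalized counts). Zero-variation genera are inert and rejected.
    """

    condition_pair: str
    genus: str
    delta: float

    def __post_init__(self) -> None:
        if not self.genus.strip():
            raise ValueError("genus must be nonempty")
        if not math.isfinite(self.delta):
            raise ValueError(f"delta for {self.genus!r} must be finite")
        if self.delta == 0:
            raise ValueError(
                f"delta for {self.genus!r} is zero; zero-variation genera "
                "carry no impact and must be dropped upstream"
            )


@dataclass(frozen=True)
class GenusAnnotation:
    """Harmful/harmless/discarded label for one genus in one condition pair."""

    condition_pair: str
    genus: str
    label: str
    evidence: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")
        if self.label == HARMFUL and not self.evidence:
            raise ValueError("harmful annotation requires species evidence")


def drop_zero_deltas(
    rows: Iterable[tuple[str, str, float]],
) -> list[DifferentialGenus]:
    """Build DifferentialGenus records, dropping zero deltas with a log line."""
    out = []
    for pair, genus, delta in rows:
        if delta == 0:
            logger.info("dropping zero-variation genus %s (%s)", genus, pair)
            continue
        out.append(DifferentialGenus(pair, genus, float(delta)))
    return out


def _annotate_one(
    genus: str,
    observed: set[str] | None,
    table: PathogenTable,
    strict_discard: bool,
) -> tuple[str, tuple[str, ...]]:
    if observed is None:
        # genus-only mode: table membership decides, nothing discarded
        if table.has_genus(genus):
            return HARMFUL, tuple(sorted(table.harmful_species_of_genus(genus)))
        return HARMLESS, ()

    if not observed:
        if table.has_genus(genus) or strict_discard:
            return DISCARDED, ()
        return HARMLESS, ()

    harmful_observed = tuple(
        sorted(sp for sp in observed if table.is_harmful_species(sp))
    )
    if harmful_observed:
        return HARMFUL, harmful_observed
    return HARMLESS, tuple(sorted(observed))


def annotate_genera(
    diffs: Sequence[DifferentialGenus],
    table: PathogenTable,
    observed_species: Mapping[str, set[str]] | None = None,
    strict_discard: bool = False,
) -> list[GenusAnnotation]:
    """Annotate every differential genus as harmful/harmless/discarded.

    Parameters
    ----------
    diffs
        Differential genus records (one per genus per condition pair).
    table
        The curated pathogen Genus-Species table.
    observed_species
        Optional genus -> set-of-species map of the species actually observed
        in the dataset (e.g. from :func:`dysbiota.classify.classify_batch`).
        When given, species mode applies; when None, genus-only mode.
    strict_discard
        In species mode, also discard genera absent from the pathogen table
        when they have no observed species (default: such genera are
        conservatively harmless).

    Returns one :class:`GenusAnnotation` per input record; every genus
    receives exactly one label.
    """
    annotations = []
    for diff in diffs:
        observed = None
        if observed_species is not None:
            observed = set(observed_species.get(diff.genus, set()))
        label, evidence = _annotate_one(
            diff.genus, observed, table, strict_discard
        )
        annotations.append(
            GenusAnnotation(
                condition_pair=diff.condition_pair,
                genus=diff.genus,
                label=label,
                evidence=evidence,
            )
        )
    counts = annotation_summary(annotations)
    logger.info(
        "annotated %d genera: %d harmless, %d harmful, %d discarded",
        len(annotations), counts[HARMLESS], counts[HARMFUL], counts[DISCARDED],
    )
    _warn_divergent_labels(annotations)
    return annotations


def _warn_divergent_labels(annotations: Sequence[GenusAnnotation]) -> None:
    """Log genera labelled differently across condition pairs of one run."""
    by_genus: dict[str, set[str]] = {}
    for ann in annotations:
        by_genus.setdefault(ann.genus, set()).add(ann.label)
    for genus, labels in sorted(by_genus.items()):
        if len(labels) > 1:
            warnings.warn(
                f"genus {genus!r} carries divergent labels across condition "
                f"pairs: {sorted(labels)}"
            )


def annotation_summary(
    annotations: Iterable[GenusAnnotation],
) -> dict[str, int]:
    """Counts per label; totals always sum to the number of annotations."""
    counts = Counter(ann.label for ann in annotations)
    return {label: counts.get(label, 0) for label in LABELS}
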