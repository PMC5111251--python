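"""Curated pathogen Genus-Species table: loading, validation and lookup.

The table encodes the binary harmful/harmless knowledge used to annotate
differential genera: a species listed here is regarded as *harmful*
(explicitly disease-associated); any species absent from the table is,
conservatively, *harmless*. The package bundles a small, documented default
table containing well-known human pathogens; users supply their own curated
table for real analyses (``--pathogen-table``).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

logger = logging.getLogger(__name__)

#: Tokens stripped when normalizing species names: everything after the
#: binomial (strain / subspecies decorations vary across reference taxonomies).
_BINOMIAL_TOKENS = 2


def normalize_name(name: str) -> str:
    """Normalize a taxon name: lowercase, collapse whitespace.

    Species names are truncated to the binomial (first two tokens), dropping
    subspecies/strain suffixes such as ``subsp. lactis`` or strain codes.
    """
    tokens = name.strip().lower().split()
    if len(tokens) > _BINOMIAL_TOKENS:
        tokens = tokens[:_BINOMIAL_TOKENS]
    return " ".join(tokens)


@dataclass(frozen=True)
class PathogenRecord:
    """One curated (genus, species) pathogen entry."""

    genus: str
    species: str

    def __post_init__(self) -> None:
        if not self.genus.strip():
            raise ValueError("genus must be nonempty")
        if not self.species.strip():
            raise ValueError("species must be nonempty")


@dataclass
class PathogenTable:
    """Set of pathogenic species, indexed for case-insensitive lookup.

    Parameters
    ----------
    records
        Validated, de-duplicated pathogen records.
    source_label
        Provenance string (file path or ``"bundled"``).
    """

    records: frozenset[PathogenRecord]
    source_label: str = "unspecified"
    _species_index: set[str] = field(init=False, repr=False)
    _genus_index: dict[str, set[str]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._species_index = set()
        self._genus_index = {}
        for rec in self.records:
            genus_key = normalize_name(rec.genus)
            species_key = normalize_name(rec.species)
            self._species_index.add(species_key)
            self._genus_index.setdefault(genus_key, set()).add(rec.species)

    def __len__(self) -> int:
        return len(self.records)

    def is_harmful_species(self, species: str) -> bool:
        """True iff the normalized species name is in the table."""
        return normalize_name(species) in self._species_index

    def has_genus(self, genus: str) -> bool:
        """True iff the genus has at least one listed harmful species."""
        return normalize_name(genus) in self._genus_index

    def harmful_species_of_genus(self, genus: str) -> set[str]:
        """All listed harmful species of a genus (empty if genus absent)."""
        return set(self._genus_index.get(normalize_name(genus), set()))

    @property
    def genera(self) -> set[str]:
        return set(self._genus_index)


def _validate_rows(
    rows: Iterable[tuple[int, str, str]],
) -> frozenset[PathogenRecord]:
    """Validate (lineno, genus, species) rows; reject genus/species mismatches.

    A species whose first token does not match its genus column is rejected
    with a warning (surfacing curation errors beats silently re-homing them).
    """
    records: set[PathogenRecord] = set()
    for lineno, genus, species in rows:
        genus_norm = normalize_name(genus)
        species_norm = normalize_name(species)
        if not genus_norm or not species_norm:
            warnings.warn(
                f"pathogen table line {lineno}: empty genus or species, skipped"
            )
            continue
        if species_norm.split()[0] != genus_norm:
            warnings.warn(
                f"pathogen table line {lineno}: species {species!r} does not "
                f"begin with genus {genus!r}; row rejected"
            )
            continue
        records.add(PathogenRecord(genus=genus.strip(), species=species.strip()))
    return frozenset(records)


def load_pathogen_table(source: str | Path | None = None) -> PathogenTable:
    """Load a Genus-Species pathogen table from tab-separated text.

    Expected format: UTF-8, header line ``Genus<TAB>Species``, one record per
    line. When *source* is None the bundled default table is loaded.

    Raises
    ------
    ValueError
        If the file is empty, lacks the two columns, or yields no valid record.
    """
    if source is None:
        ref = resources.files("dysbiota").joinpath("data/pathogen_table.tsv")
        text = ref.read_text(encoding="utf-8")
        label = "bundled"
    else:
        text = Path(source).read_text(encoding="utf-8")
        label = str(source)

    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"pathogen table {label!r} is empty")

    start = 1 if lines[0].lower().replace(" ", "").startswith("genus\t") else 0
    rows: list[tuple[int, str, str]] = []
    for lineno, line in enumerate(lines[start:], start=start + 1):
        parts = line.split("\t")
        if len(parts) < 2:
            warnings.warn(
                f"pathogen table line {lineno}: expected 2 tab-separated "
                f"columns, got {len(parts)}; skipped"
            )
            continue
        rows.append((lineno, parts[0], parts[1]))

    records = _validate_rows(rows)
    if not records:
        raise ValueError(f"pathogen table {label!r} contains no valid records")
    table = PathogenTable(records=records, source_label=label)
    logger.info(
        "loaded pathogen table %s: %d species across %d genera",
        label, len(table), len(table.genera),
    )
    return table


def write_pathogen_table(table: PathogenTable, dest: str | Path) -> None:
    """Write a pathogen table as tab-separated text (sorted, round-trippable)."""
    recs = sorted(table.records, key=lambda r: (r.genus, r.species))
    with open(dest, "w", encoding="utf-8") as fh:
        fh.write("Genus\tSpecies\n")
        for rec in recs:
            fh.write(f"{rec.genus}\t{rec.species}\n")
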