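"""Seeded generators with known ground truth for every pipeline stage.

The generators stand in for the external 16S data a real study would use:
a reference sequence set with lineages (genera as diverged root sequences,
species as lightly perturbed copies), query reads (full-length mutated copies
with a read -> species truth table), a pathogen table marking the designated
harmful species, Δg tables with planted signs and magnitudes, and count
matrices for the diversity measures. A single seed makes every output
reproducible byte for byte.

Default condition: 10 genera × 2 species, 1200 bp sequences (full-length 16S),
10% inter-genus divergence, 2% intra-genus (species) divergence, and reads
carrying 1% i.i.d. substitutions — a clean amplicon setting under which
genus-level classification is expected to be nearly always correct.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .annotate import DifferentialGenus
from .classify import reverse_complement
from .pathogens import PathogenRecord, PathogenTable

_ALPHABET = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimulationSpec:
    """Parameters of the synthetic study.

    ``genus_divergence`` is the substitution fraction between each genus root
    and the common ancestor (so two genera differ at roughly twice that
    fraction of sites); ``species_divergence`` perturbs each species from its
    genus root. ``harmful_genera`` designates which genera (0-based indices)
    have all their species listed in the generated pathogen table.
    """

    n_genera: int = 10
    species_per_genus: int = 2
    sequence_length: int = 1200
    genus_divergence: float = 0.10
    species_divergence: float = 0.02
    read_substitution_rate: float = 0.01
    reads_per_species: int = 25
    harmful_genera: tuple[int, ...] = (0, 1, 2)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("genus_divergence", "species_divergence",
                     "read_substitution_rate"):
            rate = getattr(self, name)
            if not 0 <= rate < 1:
                raise ValueError(f"{name} must be in [0, 1)")
        if self.n_genera < 1 or self.species_per_genus < 1:
            raise ValueError("need at least one genus with one species")
        if self.sequence_length < 1:
            raise ValueError("sequence_length must be positive")
        if any(not 0 <= g < self.n_genera for g in self.harmful_genera):
            raise ValueError("harmful_genera indices out of range")

    def genus_name(self, i: int) -> str:
        return f"Simgenus{i + 1:02d}"

    def species_name(self, i: int, j: int) -> str:
        return f"{self.genus_name(i)} sp{j + 1:02d}"


@dataclass
class SyntheticReference:
    """A generated reference set: sequences, lineages, pathogen table, truth."""

    spec: SimulationSpec
    sequences: dict[str, str]
    lineages: dict[str, str]                # id -> "domain;...;species"
    pathogen_table: PathogenTable
    harmful_genera: set[str]
    species_of_genus: dict[str, list[str]] = field(default_factory=dict)

    @property
    def genera(self) -> list[str]:
        return list(self.species_of_genus)


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """i.i.d. substitutions at the given rate; mutated sites change base."""
    if rate == 0:
        return seq.copy()
    out = seq.copy()
    hits = np.nonzero(rng.random(seq.size) < rate)[0]
    if hits.size:
        # shift by 1..3 in base space: guaranteed different base
        shift = rng.integers(1, 4, size=hits.size)
        idx = (np.searchsorted(_ALPHABET, out[hits]) + shift) % 4
        out[hits] = _ALPHABET[idx]
    return out


def _to_str(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def simulate_reference(spec: SimulationSpec) -> SyntheticReference:
    """Generate a reference FASTA-equivalent set with consistent taxonomy.

    Genera are mutated copies of one random ancestor (at
    ``genus_divergence``); species are copies of their genus root (at
    ``species_divergence``). Half the genera are placed in Firmicutes, half
    in Bacteroidetes, so phylum-level measures are exercised too. All species
    of the designated harmful genera are listed in the returned pathogen
    table.
    """
    if spec.genus_divergence == 0 and spec.n_genera > 1:
        warnings.warn("genus_divergence is 0: genera are indistinguishable")
    rng = np.random.default_rng(spec.seed)
    ancestor = rng.choice(_ALPHABET, size=spec.sequence_length)

    sequences: dict[str, str] = {}
    lineages: dict[str, str] = {}
    species_of_genus: dict[str, list[str]] = {}
    records: set[PathogenRecord] = set()
    harmful_names: set[str] = set()

    for i in range(spec.n_genera):
        genus = spec.genus_name(i)
        phylum = "Firmicutes" if i % 2 == 0 else "Bacteroidetes"
        root = _mutate(ancestor, spec.genus_divergence, rng)
        species_of_genus[genus] = []
        if i in spec.harmful_genera:
            harmful_names.add(genus)
        for j in range(spec.species_per_genus):
            species = spec.species_name(i, j)
            seq_id = f"ref_{i + 1:02d}_{j + 1:02d}"
            sequences[seq_id] = _to_str(_mutate(root, spec.species_divergence, rng))
            lineages[seq_id] = ";".join(
                [
                    "Bacteria",
                    phylum,
                    f"Simclass_{phylum}",
                    f"Simorder_{phylum}",
                    f"Simfamily{i + 1:02d}",
                    genus,
                    species,
                ]
            )
            species_of_genus[genus].append(species)
            if i in spec.harmful_genera:
                records.add(PathogenRecord(genus=genus, species=species))

    table = PathogenTable(records=frozenset(records), source_label="synthetic")
    return SyntheticReference(
        spec=spec,
        sequences=sequences,
        lineages=lineages,
        pathogen_table=table,
        harmful_genera=harmful_names,
        species_of_genus=species_of_genus,
    )


def simulate_reads(
    reference: SyntheticReference,
    reads_per_species: Mapping[str, int] | int | None = None,
    substitution_rate: float | None = None,
    seed: int | None = None,
    revcomp_fraction: float = 0.0,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Full-length mutated reads from reference species, with a truth table.

    Returns ``(reads, truth)`` where reads are (read_id, sequence) pairs and
    truth maps each read to its source sequence, species and genus. Reads per
    species may be a single integer (same depth everywhere) or a mapping from
    species name to count; species absent from the mapping get no reads.
    """
    spec = reference.spec
    if substitution_rate is None:
        substitution_rate = spec.read_substitution_rate
    if not 0 <= substitution_rate < 1:
        raise ValueError("substitution_rate must be in [0, 1)")
    if seed is None:
        seed = spec.seed + 1
    rng = np.random.default_rng(seed)

    species_lineage = {}
    seqs_of_species: dict[str, list[str]] = {}
    for seq_id, lin in reference.lineages.items():
        parts = lin.split(";")
        species_lineage[parts[-1]] = (parts[-2], parts[-1])
        seqs_of_species.setdefault(parts[-1], []).append(seq_id)

    if reads_per_species is None:
        reads_per_species = spec.reads_per_species
    if isinstance(reads_per_species, int):
        counts = {sp: reads_per_species for sp in sorted(species_lineage)}
    else:
        unknown = sorted(set(reads_per_species) - set(species_lineage))
        if unknown:
            raise ValueError(f"unknown species in read counts: {unknown[:5]}")
        counts = {sp: int(n) for sp, n in sorted(reads_per_species.items())}

    reads: list[tuple[str, str]] = []
    truth_rows = []
    k = 0
    for species, n in counts.items():
        genus, _ = species_lineage[species]
        for _ in range(n):
            src = seqs_of_species[species][k % len(seqs_of_species[species])]
            base = np.frombuffer(
                reference.sequences[src].encode("ascii"), dtype=np.uint8
            )
            seq = _to_str(_mutate(base, substitution_rate, rng))
            orientation = "forward"
            if revcomp_fraction > 0 and rng.random() < revcomp_fraction:
                seq = reverse_complement(seq)
                orientation = "reverse"
            read_id = f"read_{k + 1:05d}"
            reads.append((read_id, seq))
            truth_rows.append(
                {
                    "read_id": read_id,
                    "source_id": src,
                    "species": species,
                    "genus": genus,
                    "orientation": orientation,
                }
            )
            k += 1
    truth = pd.DataFrame(
        truth_rows,
        columns=["read_id", "source_id", "species", "genus", "orientation"],
    )
    return reads, truth


@dataclass
class SyntheticExperiment:
    """A planted differential experiment with its expected outcomes."""

    diffs: list[DifferentialGenus]
    expected_labels: dict[str, str]             # genus -> harmful|harmless
    expected_contingency: pd.DataFrame          # pairs x (eubiotic, dysbiotic)
    observed_species: dict[str, set[str]]       # ground-truth species map


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def simulate_diff_experiment(
    reference: SyntheticReference,
    effects: Mapping[str, Mapping[str, float]] | None = None,
    condition_pairs: tuple[str, ...] = ("case-control",),
    delta_range: tuple[float, float] = (5.0, 50.0),
    seed: int | None = None,
) -> SyntheticExperiment:
    """Plant a Δg table and compute its expected impact by direct arithmetic.

    ``effects`` maps condition pair -> genus -> signed Δg; omitted pairs (or
    ``effects=None``) draw each genus's Δg uniformly from ±``delta_range``.
    The expected contingency is computed straight from the planted harmful /
    harmless designations and signs — increase of harmless plus decrease of
    harmful is eubiotic, the converse dysbiotic — independent of the impact
    module, so it can serve as its oracle.
    """
    spec = reference.spec
    if seed is None:
        seed = spec.seed + 2
    rng = np.random.default_rng(seed)
    if effects is not None:
        condition_pairs = tuple(effects)

    expected_labels = {
        g: ("harmful" if g in reference.harmful_genera else "harmless")
        for g in reference.genera
    }

    diffs: list[DifferentialGenus] = []
    rows = {}
    for pair in condition_pairs:
        eub = 0.0
        total = 0.0
        genus_effects = (effects or {}).get(pair)
        for genus in reference.genera:
            if genus_effects is not None:
                if genus not in genus_effects:
                    continue
                delta = float(genus_effects[genus])
            else:
                magnitude = rng.uniform(*delta_range)
                delta = magnitude * (1 if rng.random() < 0.5 else -1)
            if delta == 0:
                continue
            diffs.append(DifferentialGenus(pair, genus, delta))
            harmful = expected_labels[genus] == "harmful"
            eubiotic = (delta > 0) != harmful  # harmless up or harmful down
            total += abs(delta)
            if eubiotic:
                eub += abs(delta)
        eub_r = _round_half_up(eub)
        rows[pair] = (eub_r, _round_half_up(total) - eub_r)

    expected = pd.DataFrame.from_dict(
        rows, orient="index", columns=["eubiotic", "dysbiotic"]
    )
    observed = {g: set(sps) for g, sps in reference.species_of_genus.items()}
    return SyntheticExperiment(
        diffs=diffs,
        expected_labels=expected_labels,
        expected_contingency=expected,
        observed_species=observed,
    )


def simulate_phylum_counts(
    n_samples_per_arm: Mapping[str, int],
    fb_ratio_per_arm: Mapping[str, float],
    depth: int = 20000,
    dispersion: float = 0.1,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Two-phylum count matrix with planted per-arm Firmicutes/Bacteroidetes ratios.

    Per-sample ratios are log-normally scattered around the arm's target
    (``dispersion`` = sdlog), counts drawn from a multinomial at the given
    depth. Returns the samples × phyla matrix and the sample -> arm labels.
    """
    rng = np.random.default_rng(seed)
    rows = {}
    labels = {}
    for arm, n in n_samples_per_arm.items():
        target = fb_ratio_per_arm[arm]
        for s in range(n):
            ratio = target * float(np.exp(rng.normal(0.0, dispersion)))
            p_f = ratio / (1.0 + ratio)
            f, b = rng.multinomial(depth, [p_f, 1.0 - p_f])
            sample = f"{arm}_{s + 1:02d}"
            rows[sample] = (f, b)
            labels[sample] = arm
    matrix = pd.DataFrame.from_dict(
        rows, orient="index", columns=["Firmicutes", "Bacteroidetes"]
    )
    return matrix, pd.Series(labels, name="arm")


def reproducibility_header(spec: SimulationSpec) -> str:
    """One-line comment header recording the generating spec."""
    fields = ", ".join(f"{k}={v}" for k, v in vars(spec).items())
    return f"# dysbiota synthetic data | {fields}"


def write_reference(
    reference: SyntheticReference, outdir: str | Path
) -> dict[str, Path]:
    """Write reference FASTA, taxonomy, and pathogen table files."""
    from .io import write_fasta
    from .pathogens import write_pathogen_table

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "reference": outdir / "reference.fasta",
        "taxonomy": outdir / "taxonomy.tsv",
        "pathogen_table": outdir / "pathogen_table.tsv",
    }
    write_fasta(reference.sequences.items(), paths["reference"])
    header = reproducibility_header(reference.spec)
    with open(paths["taxonomy"], "w", encoding="utf-8") as fh:
        fh.write(header + "\n")
        for seq_id in reference.sequences:
            fh.write(f"{seq_id}\t{reference.lineages[seq_id]}\n")
    write_pathogen_table(reference.pathogen_table, paths["pathogen_table"])
    return paths
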