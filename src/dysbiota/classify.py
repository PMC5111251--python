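"""Species-level 16S taxonomic classification, Wang-style naive Bayes.

Reference sequences are decomposed into overlapping k-mers ("words", k=8 by
default) counted as present/absent per sequence. For a taxon t with M(t)
training sequences, the conditional probability of word w is smoothed as

    P(w | t) = (m(w, t) + 0.5) / (M(t) + 1)

where m(w, t) is the number of sequences of t containing w. A query is scored
against every species-level taxon by the sum of log P(w|t) over its distinct
words (naive-Bayes log posterior with a flat prior); the argmax species and
its full lineage are assigned. Assignment stability is quantified by
bootstrap: ⌊W/k⌋ of the query's W distinct words are resampled with
replacement (100 trials by default) and the per-rank confidence is the
percentage of trials whose assignment agrees with the full-word assignment on
the lineage prefix down to that rank, which makes confidences monotonically
non-increasing from domain to species. Ranks below the confidence cutoff are
reported as unclassified.

Both orientations of each query are scored and the better one kept, since
amplicon read orientation is not guaranteed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")

DEFAULT_KMER_SIZE = 8
DEFAULT_N_BOOTSTRAP = 100
DEFAULT_CONFIDENCE_CUTOFF = 80

_BASE_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i
    _BASE_CODE[_b + 32] = _i  # lowercase

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _distinct_words(seq: str, k: int) -> np.ndarray:
    """Distinct k-mer codes (base-4 integers) of a sequence.

    Windows containing non-ACGT characters (N etc.) are skipped.
    """
    codes = _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if codes.size < k:
        return np.empty(0, dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(codes, k).astype(np.int64)
    valid = (win >= 0).all(axis=1)
    if not valid.any():
        return np.empty(0, dtype=np.int64)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    return np.unique(win[valid] @ powers)


@dataclass
class TaxAssignment:
    """Classification result for one query sequence."""

    query_id: str
    ranks: tuple[str, ...]
    lineage: tuple[str, ...]
    confidence: tuple[int, ...]
    orientation: str = "forward"  # or "reverse"
    log_score: float = float("nan")

    def classified_lineage(self, cutoff: int) -> tuple[str | None, ...]:
        """Lineage with ranks below the bootstrap-confidence cutoff masked."""
        return tuple(
            name if conf >= cutoff else None
            for name, conf in zip(self.lineage, self.confidence)
        )

    @property
    def is_unclassified(self) -> bool:
        return all(c == 0 for c in self.confidence)

    def rank_value(self, rank: str, cutoff: int = 0) -> str | None:
        idx = self.ranks.index(rank)
        name, conf = self.lineage[idx], self.confidence[idx]
        return name if name and conf >= cutoff else None

    def to_line(self) -> str:
        parts = [
            f"{name or 'unclassified'}({conf})"
            for name, conf in zip(self.lineage, self.confidence)
        ]
        return f"{self.query_id}\t{';'.join(parts)}"


def _unclassified(query_id: str, ranks: Sequence[str]) -> TaxAssignment:
    return TaxAssignment(
        query_id=query_id,
        ranks=tuple(ranks),
        lineage=tuple("" for _ in ranks),
        confidence=tuple(0 for _ in ranks),
    )


@dataclass
class ReferenceTaxonomyDB:
    """k-mer word statistics of a reference 16S sequence set.

    Taxa are the species-level lineages; each carries a log-probability row
    over the words observed anywhere in the reference, plus a default
    log-probability log(0.5/(M+1)) for unseen words.
    """

    kmer_size: int
    ranks: tuple[str, ...]
    taxon_names: list[str]                 # species names, lexicographic
    lineages: list[tuple[str, ...]]        # per taxon, one name per rank
    seq_counts: np.ndarray                 # M(t), shape (T,)
    vocab: np.ndarray = field(repr=False)  # sorted word codes, shape (V,)
    log_prob: np.ndarray = field(repr=False)       # (T, V)
    log_prob_unseen: np.ndarray = field(repr=False)  # (T,)
    n_sequences: int = 0

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_names)

    def word_log_probs(self, words: np.ndarray) -> np.ndarray:
        """Log P(w|t) matrix for the given word codes, shape (T, len(words))."""
        pos = np.searchsorted(self.vocab, words)
        pos_clipped = np.minimum(pos, len(self.vocab) - 1)
        seen = self.vocab[pos_clipped] == words
        out = np.repeat(self.log_prob_unseen[:, None], len(words), axis=1)
        if seen.any():
            out[:, seen] = self.log_prob[:, pos_clipped[seen]]
        return out


def parse_lineage(lineage: str) -> tuple[str, ...]:
    """Split a ``domain;phylum;...;species`` lineage string."""
    return tuple(part.strip() for part in lineage.split(";"))


def build_reference_index(
    sequences: dict[str, str],
    lineages: dict[str, str | Sequence[str]],
    kmer_size: int = DEFAULT_KMER_SIZE,
    ranks: Sequence[str] = RANKS,
) -> ReferenceTaxonomyDB:
    """Build the per-taxon word-occurrence index from reference sequences.

    Parameters
    ----------
    sequences
        Mapping of sequence id to nucleotide string (A/C/G/T/N).
    lineages
        Mapping of sequence id to its lineage, either a ``;``-separated
        string or a sequence of rank names; depth must equal ``len(ranks)``.
    kmer_size
        Word length (k >= 1).

    Raises
    ------
    ValueError
        On id mismatch between sequences and lineages, inconsistent lineage
        depth, or an empty reference set.
    """
    if kmer_size < 1:
        raise ValueError("kmer_size must be >= 1")
    if not sequences:
        raise ValueError("empty reference sequence set")
    missing = sorted(set(sequences) - set(lineages))
    extra = sorted(set(lineages) - set(sequences))
    if missing or extra:
        raise ValueError(
            "sequence/taxonomy id mismatch: "
            f"ids without lineage: {missing[:10]}; "
            f"lineages without sequence: {extra[:10]}"
        )

    ranks = tuple(ranks)
    taxon_of_seq: dict[str, tuple[str, ...]] = {}
    for seq_id in sequences:
        lin = lineages[seq_id]
        lin_t = parse_lineage(lin) if isinstance(lin, str) else tuple(lin)
        if len(lin_t) != len(ranks):
            raise ValueError(
                f"lineage for {seq_id!r} has depth {len(lin_t)}, "
                f"expected {len(ranks)}"
            )
        taxon_of_seq[seq_id] = lin_t

    taxa = sorted({lin for lin in taxon_of_seq.values()}, key=lambda t: t[-1])
    taxon_index = {lin: i for i, lin in enumerate(taxa)}

    word_sets: list[list[np.ndarray]] = [[] for _ in taxa]
    seq_counts = np.zeros(len(taxa), dtype=np.int64)
    for seq_id, seq in sequences.items():
        words = _distinct_words(seq, kmer_size)
        if words.size == 0:
            warnings.warn(
                f"reference sequence {seq_id!r} contributes zero words "
                f"(shorter than k={kmer_size} or all-ambiguous)"
            )
        t = taxon_index[taxon_of_seq[seq_id]]
        seq_counts[t] += 1
        if words.size:
            word_sets[t].append(words)

    vocab = np.unique(np.concatenate(
        [w for ws in word_sets for w in ws] or [np.empty(0, dtype=np.int64)]
    ))
    m = np.zeros((len(taxa), vocab.size), dtype=np.float64)
    for t, ws in enumerate(word_sets):
        for words in ws:
            m[t, np.searchsorted(vocab, words)] += 1.0

    denom = (seq_counts + 1.0)[:, None]
    log_prob = np.log((m + 0.5) / denom)
    log_prob_unseen = np.log(0.5 / (seq_counts + 1.0))

    db = ReferenceTaxonomyDB(
        kmer_size=kmer_size,
        ranks=ranks,
        taxon_names=[t[-1] for t in taxa],
        lineages=list(taxa),
        seq_counts=seq_counts,
        vocab=vocab,
        log_prob=log_prob,
        log_prob_unseen=log_prob_unseen,
        n_sequences=len(sequences),
    )
    logger.info(
        "reference index: %d sequences, %d species taxa, %d distinct %d-mers",
        db.n_sequences, db.n_taxa, vocab.size, kmer_size,
    )
    return db


def _argmax_lex(scores: np.ndarray) -> int:
    # taxa are stored in lexicographic species order, so the first argmax
    # is the lexicographic tie-break
    return int(np.argmax(scores))


def classify(
    query: str,
    db: ReferenceTaxonomyDB,
    query_id: str = "query",
    n_bootstrap: int = DEFAULT_N_BOOTSTRAP,
    confidence_cutoff: int = DEFAULT_CONFIDENCE_CUTOFF,
    seed: int | np.random.Generator | None = 0,
) -> TaxAssignment:
    """Classify one query sequence against the reference index.

    Returns a :class:`TaxAssignment` with the full-word lineage and per-rank
    bootstrap confidences; use ``classified_lineage(confidence_cutoff)`` for
    the cutoff-masked lineage. A query with no usable words (e.g. all-N) is
    returned unclassified at every rank.

    Raises
    ------
    ValueError
        If the query is shorter than the word size or the index is empty.
    """
    if db.n_taxa == 0:
        raise ValueError("empty reference index")
    if len(query) < db.kmer_size:
        raise ValueError(
            f"query {query_id!r} shorter than kmer_size={db.kmer_size}"
        )
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )

    fwd = _distinct_words(query, db.kmer_size)
    rev = _distinct_words(reverse_complement(query), db.kmer_size)
    if fwd.size == 0 and rev.size == 0:
        logger.info("query %s: no usable words, unclassified", query_id)
        return _unclassified(query_id, db.ranks)

    best: tuple[float, str, np.ndarray, np.ndarray] | None = None
    for orientation, words in (("forward", fwd), ("reverse", rev)):
        if words.size == 0:
            continue
        lp = db.word_log_probs(words)           # (T, W)
        scores = lp.sum(axis=1)
        top = scores[_argmax_lex(scores)]
        if best is None or top > best[0]:
            best = (top, orientation, words, lp)
    assert best is not None
    top_score, orientation, words, lp = best
    full_idx = _argmax_lex(lp.sum(axis=1))
    full_lineage = db.lineages[full_idx]

    w = words.size
    n_sub = max(1, w // db.kmer_size)
    if n_bootstrap > 0:
        picks = rng.integers(0, w, size=(n_bootstrap, n_sub))
        # (T, B, S) -> (T, B)
        boot_scores = lp[:, picks].sum(axis=2)
        boot_idx = np.argmax(boot_scores, axis=0)  # first max = lex tie-break
        agree = np.zeros(len(db.ranks), dtype=np.int64)
        boot_lineages = [db.lineages[i] for i in boot_idx]
        for blin in boot_lineages:
            depth = 0
            for a, b in zip(blin, full_lineage):
                if a != b:
                    break
                depth += 1
            agree[:depth] += 1
        confidence = tuple(
            int(round(100.0 * a / n_bootstrap)) for a in agree
        )
    else:
        confidence = tuple(100 for _ in db.ranks)

    return TaxAssignment(
        query_id=query_id,
        ranks=db.ranks,
        lineage=full_lineage,
        confidence=confidence,
        orientation=orientation,
        log_score=float(top_score),
    )


def classify_batch(
    queries: Iterable[tuple[str, str]],
    db: ReferenceTaxonomyDB,
    n_bootstrap: int = DEFAULT_N_BOOTSTRAP,
    confidence_cutoff: int = DEFAULT_CONFIDENCE_CUTOFF,
    seed: int = 0,
) -> tuple[list[TaxAssignment], dict[str, set[str]]]:
    """Classify (id, sequence) records; aggregate an observed-species map.

    Returns the per-query assignments plus a genus -> {species} map built
    from assignments whose species-rank confidence reaches the cutoff. The
    map is the ``observed_species`` input of the annotation stage.

    Each query gets its own RNG stream derived from *seed*, so results do
    not depend on batch order or size.
    """
    queries = list(queries)
    if not queries:
        warnings.warn("classify_batch: empty query set")
        return [], {}
    root = np.random.SeedSequence(seed)
    streams = root.spawn(len(queries))
    assignments: list[TaxAssignment] = []
    species_map: dict[str, set[str]] = {}
    genus_i = db.ranks.index("genus")
    species_i = db.ranks.index("species")
    for (query_id, seq), ss in zip(queries, streams):
        asn = classify(
            seq, db, query_id=query_id, n_bootstrap=n_bootstrap,
            confidence_cutoff=confidence_cutoff,
            seed=np.random.default_rng(ss),
        )
        assignments.append(asn)
        if asn.confidence[species_i] >= confidence_cutoff and asn.lineage[species_i]:
            species_map.setdefault(asn.lineage[genus_i], set()).add(
                asn.lineage[species_i]
            )
    return assignments, species_map


def write_assignments(assignments: Iterable[TaxAssignment], dest: str | Path) -> None:
    """Write per-read classifications as ``query_id<TAB>lineage(conf);...``."""
    with open(dest, "w", encoding="utf-8") as fh:
        for asn in assignments:
            fh.write(asn.to_line() + "\n")


def write_species_map(species_map: dict[str, set[str]], dest: str | Path) -> None:
    """Write the genus -> observed species map as tab-separated text."""
    with open(dest, "w", encoding="utf-8") as fh:
        fh.write("Genus\tSpecies\n")
        for genus in sorted(species_map):
            for sp in sorted(species_map[genus]):
                fh.write(f"{genus}\t{sp}\n")


def read_species_map(path: str | Path) -> dict[str, set[str]]:
    """Read a genus -> species map written by :func:`write_species_map`."""
    out: dict[str, set[str]] = {}
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    start = 1 if lines and lines[0].lower().startswith("genus\t") else 0
    for lineno, line in enumerate(lines[start:], start=start + 1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"species map line {lineno}: expected 2 columns")
        out.setdefault(parts[0], set()).add(parts[1])
    return out
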