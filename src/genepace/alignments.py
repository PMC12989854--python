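"""Codon-aware alignment filtering.

Per-gene multiple sequence alignments of protein-coding nucleotide
sequences are brought into reading frame, cleared of internal stop
codons, stripped of unreliable codon columns, and screened for
information content before any distances are computed.  Every gene
either survives with a :class:`CodonAlignment` or is accounted for with
a :class:`GeneRejectionRecord`, so batch runs never lose genes silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache
from itertools import product
from typing import Iterable, Sequence

from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.Data.IUPACData import ambiguous_dna_values

__all__ = [
    "CodonAlignment",
    "GeneRejectionRecord",
    "NoFrameFound",
    "EmptyAlignment",
    "detect_reading_frame",
    "mask_internal_stops",
    "filter_codon_columns",
    "count_parsimony_informative",
    "preprocess_gene",
]

STOP_CODONS = frozenset(unambiguous_dna_by_id[1].stop_codons)  # universal code
_FORWARD_TABLE = dict(unambiguous_dna_by_id[1].forward_table)
_BASES = frozenset("ACGT")


class NoFrameFound(ValueError):
    """No offset in {0,1,2} leaves a majority of taxa ending in a stop."""


class EmptyAlignment(ValueError):
    """All codon columns were removed by the column filters."""


@dataclass(frozen=True)
class CodonAlignment:
    """An in-frame, per-gene nucleotide alignment.

    Parameters
    ----------
    gene_id:
        Identifier of the gene (typically the FASTA file stem).
    taxa:
        Ordered, unique taxon labels.
    sequences:
        Upper-case aligned sequences over ``A,C,G,T``, IUPAC ambiguity
        codes and ``-``; all of identical length.
    frame_offset:
        Number of leading bases removed to restore the reading frame.
    masked_codons:
        Count of internal stop codons replaced by gap codons.
    """

    gene_id: str
    taxa: tuple[str, ...]
    sequences: tuple[str, ...]
    frame_offset: int = 0
    masked_codons: int = 0

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.sequences):
            raise ValueError("taxa and sequences differ in length")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError(f"duplicate taxon labels in gene {self.gene_id}")
        if len(self.taxa) < 2:
            raise ValueError("alignment needs at least 2 taxa")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError("sequences have unequal lengths")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_sites(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    @property
    def n_codons(self) -> int:
        return self.n_sites // 3

    def codon(self, taxon_index: int, codon_index: int) -> str:
        return self.sequences[taxon_index][codon_index * 3 : codon_index * 3 + 3]


@dataclass(frozen=True)
class GeneRejectionRecord:
    """Audit entry for a gene removed by the filters."""

    gene_id: str
    reason: str  # too_few_taxa | no_frame_found | low_information
    detail: str = ""


@lru_cache(maxsize=None)
def expand_codon(codon: str) -> tuple[str, ...]:
    """All unambiguous codons compatible with an IUPAC-ambiguous codon.

    Codons containing gaps (or any non-IUPAC character) expand to
    nothing: they are treated as unknown rather than as a set of states.
    """
    sets = []
    for base in codon:
        expansion = ambiguous_dna_values.get(base)
        if expansion is None or base == "-":
            return ()
        sets.append(expansion)
    return tuple("".join(p) for p in product(*sets))


@lru_cache(maxsize=None)
def codon_amino_acids(codon: str) -> frozenset[str]:
    """Distinct amino acids (``*`` for stop) among a codon's expansions."""
    out = set()
    for c in expand_codon(codon):
        out.add(_FORWARD_TABLE.get(c, "*"))
    return frozenset(out)


def _is_certain_stop(codon: str) -> bool:
    expansions = expand_codon(codon)
    return bool(expansions) and all(c in STOP_CODONS for c in expansions)


def _trim_to_frame(sequences: Sequence[str], offset: int) -> list[str]:
    """Drop ``offset`` leading columns and trailing columns beyond a codon."""
    length = len(sequences[0]) - offset
    length -= length % 3
    return [s[offset : offset + length] for s in sequences]


def detect_reading_frame(sequences: Sequence[str]) -> int:
    """Find the frame offset that makes alignments end in a stop codon.

    Returns the smallest offset in ``{0, 1, 2}`` such that, after
    trimming, the final codon is a stop (TAA/TAG/TGA) in every taxon
    whose final codon is free of gaps and ambiguity.  If no offset
    satisfies that for all such taxa, the offset maximizing the fraction
    of ungapped terminal stops is returned provided the fraction is at
    least one half; otherwise :class:`NoFrameFound` is raised.
    """
    if not sequences or len(sequences[0]) < 3:
        raise NoFrameFound("alignment shorter than one codon")
    best_offset = None
    best_fraction = -1.0
    for offset in (0, 1, 2):
        trimmed = _trim_to_frame(sequences, offset)
        if not trimmed[0]:
            continue
        evaluable = 0
        stops = 0
        for seq in trimmed:
            terminal = seq[-3:]
            if set(terminal) <= _BASES:
                evaluable += 1
                if terminal in STOP_CODONS:
                    stops += 1
        if evaluable == 0:
            continue
        if stops == evaluable:
            return offset
        fraction = stops / evaluable
        if fraction > best_fraction:
            best_fraction = fraction
            best_offset = offset
    if best_offset is not None and best_fraction >= 0.5:
        return best_offset
    raise NoFrameFound(
        f"no frame offset yields terminal stop codons (best fraction "
        f"{max(best_fraction, 0.0):.2f})"
    )


def mask_internal_stops(alignment: CodonAlignment) -> CodonAlignment:
    """Replace internal stop codons by gap codons; drop a terminal stop.

    A codon is masked only when *every* IUPAC expansion of it is a stop
    under the universal code, so ambiguous codons that may encode an
    amino acid are left alone.  The terminal codon column triplet is
    removed for all taxa whenever at least one unambiguous terminal
    codon is a stop, which keeps re-running the operation a no-op.
    """
    n_codons = alignment.n_codons
    masked = 0
    has_terminal_stop = any(
        alignment.codon(t, n_codons - 1) in STOP_CODONS
        for t in range(alignment.n_taxa)
    )
    last = n_codons - 1 if has_terminal_stop else n_codons
    new_sequences = []
    for t in range(alignment.n_taxa):
        codons = []
        for c in range(last):
            codon = alignment.codon(t, c)
            if _is_certain_stop(codon):
                codons.append("---")
                masked += 1
            else:
                codons.append(codon)
        new_sequences.append("".join(codons))
    return replace(
        alignment,
        sequences=tuple(new_sequences),
        masked_codons=alignment.masked_codons + masked,
    )


def _codon_is_heterozygous(codon: str) -> bool:
    """True when ambiguity expansions translate to >1 distinct amino acid."""
    if set(codon) <= _BASES:
        return False
    amino_acids = codon_amino_acids(codon)
    return len(amino_acids) > 1


def filter_codon_columns(
    alignment: CodonAlignment,
    max_gap_frac: float = 0.5,
    max_het_frac: float = 0.5,
) -> CodonAlignment:
    """Drop codon columns that are mostly gapped or mostly heterozygous.

    A codon column is removed for all taxa when the fraction of taxa
    whose codon contains a gap exceeds ``max_gap_frac``, or when the
    fraction of heterozygous codons among the non-gapped taxa exceeds
    ``max_het_frac``.  Both comparisons are strict.  Gap fractions are
    taken over all taxa; heterozygosity only over taxa without a gap in
    that codon, so gapped columns are not penalized twice.
    """
    keep: list[int] = []
    n = alignment.n_taxa
    for c in range(alignment.n_codons):
        codons = [alignment.codon(t, c) for t in range(n)]
        gapped = sum("-" in codon for codon in codons)
        if gapped / n > max_gap_frac:
            continue
        ungapped = [codon for codon in codons if "-" not in codon]
        if ungapped:
            het = sum(_codon_is_heterozygous(codon) for codon in ungapped)
            if het / len(ungapped) > max_het_frac:
                continue
        keep.append(c)
    if not keep:
        raise EmptyAlignment(f"all codon columns removed in gene {alignment.gene_id}")
    new_sequences = tuple(
        "".join(alignment.codon(t, c) for c in keep) for t in range(n)
    )
    return replace(alignment, sequences=new_sequences)


def count_parsimony_informative(sequences: Iterable[str]) -> int:
    """Number of parsimony-informative nucleotide columns.

    A column is informative when at least two distinct unambiguous
    bases are each carried by at least two taxa.  Gaps and ambiguity
    codes never count as states.
    """
    seqs = list(sequences)
    if not seqs:
        return 0
    count = 0
    for column in zip(*seqs):
        tally: dict[str, int] = {}
        for base in column:
            if base in _BASES:
                tally[base] = tally.get(base, 0) + 1
        if sum(v >= 2 for v in tally.values()) >= 2:
            count += 1
    return count


def preprocess_gene(
    gene_id: str,
    taxa: Sequence[str],
    sequences: Sequence[str],
    min_taxa: int = 9,
    min_pis: int = 10,
    max_gap_frac: float = 0.5,
    max_het_frac: float = 0.5,
    frame_offset: int | None = None,
) -> CodonAlignment | GeneRejectionRecord:
    """Run the full per-gene filter cascade.

    Order of application: taxon-count filter, frame detection and
    trimming, internal-stop masking, codon-column filters, and the
    parsimony-informative-sites filter.  Failures are returned as
    :class:`GeneRejectionRecord` rather than raised, so a batch over
    thousands of genes always completes.  Passing ``frame_offset``
    (e.g. from an alignment already processed once) skips frame
    detection, which makes the cascade idempotent on its own output.
    """
    if len(taxa) < min_taxa:
        return GeneRejectionRecord(
            gene_id, "too_few_taxa", f"{len(taxa)} < {min_taxa} taxa"
        )
    try:
        offset = (
            frame_offset
            if frame_offset is not None
            else detect_reading_frame(sequences)
        )
    except NoFrameFound as exc:
        return GeneRejectionRecord(gene_id, "no_frame_found", str(exc))
    trimmed = _trim_to_frame(sequences, offset)
    alignment = CodonAlignment(
        gene_id=gene_id,
        taxa=tuple(taxa),
        sequences=tuple(trimmed),
        frame_offset=offset,
    )
    alignment = mask_internal_stops(alignment)
    try:
        alignment = filter_codon_columns(alignment, max_gap_frac, max_het_frac)
    except EmptyAlignment as exc:
        return GeneRejectionRecord(gene_id, "low_information", str(exc))
    pis = count_parsimony_informative(alignment.sequences)
    if pis < min_pis:
        return GeneRejectionRecord(
            gene_id, "low_information", f"{pis} < {min_pis} parsimony-informative sites"
        )
    return alignment


def preprocess_batch(
    genes: dict[str, tuple[Sequence[str], Sequence[str]]],
    **kwargs,
) -> tuple[dict[str, CodonAlignment], list[GeneRejectionRecord]]:
    """Preprocess genes in sorted gene_id order for deterministic logs."""
    accepted: dict[str, CodonAlignment] = {}
    rejected: list[GeneRejectionRecord] = []
    for gene_id in sorted(genes):
        taxa, sequences = genes[gene_id]
        result = preprocess_gene(gene_id, taxa, sequences, **kwargs)
        if isinstance(result, CodonAlignment):
            accepted[gene_id] = result
        else:
            rejected.append(result)
    return accepted, rejected
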