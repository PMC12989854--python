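"""Per-gene pairwise evolutionary distances.

Implements raw Hamming (p-) distances and the Nei–Gojobori (1986)
counting estimator of synonymous (dS) and non-synonymous (dN) distances
with Jukes–Cantor correction, assembles them into genes × taxa × taxa
tensors on a common taxon panel, and imports externally computed
matrices (e.g. codeml ML distances or gene-tree cophenetic matrices)
for exact replication.

NG86 conventions used here: synonymous site fractions are computed per
codon position over the non-stop single-nucleotide neighbours, so that
N_sites + S_sites is exactly three times the number of compared codons;
substitution paths between codon pairs that traverse a stop codon are
excluded, and differences are averaged over the remaining shortest
paths.  These are common NG86 variants but variants differ, hence the
explicit statement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import combinations, permutations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .alignments import CodonAlignment, STOP_CODONS, _FORWARD_TABLE, _BASES

__all__ = [
    "GeneDistanceMatrix",
    "DistanceTensor",
    "FrameError",
    "EmptyPanel",
    "NG86Result",
    "ng86_pair",
    "hamming_matrix",
    "ng86_matrices",
    "build_distance_tensors",
    "import_distance_matrices",
    "jukes_cantor",
]

_NUCS = "ACGT"
SENSE_CODONS = tuple(
    a + b + c
    for a in _NUCS
    for b in _NUCS
    for c in _NUCS
    if a + b + c not in STOP_CODONS
)


class FrameError(ValueError):
    """Sequences are unequal in length or not divisible by three."""


class EmptyPanel(ValueError):
    """No genes survive tensor assembly."""


def _translate(codon: str) -> str:
    return _FORWARD_TABLE.get(codon, "*")


@lru_cache(maxsize=None)
def synonymous_sites(codon: str) -> float:
    """NG86 synonymous site count of one sense codon.

    Each position contributes the fraction of synonymous changes among
    its single-nucleotide neighbours that are not stop codons; each
    position contributes one site in total, so the codon always carries
    three sites split between synonymous and non-synonymous.
    """
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon} has no site counts")
    aa = _translate(codon)
    s = 0.0
    for pos in range(3):
        valid = 0
        syn = 0
        for base in _NUCS:
            if base == codon[pos]:
                continue
            neighbour = codon[:pos] + base + codon[pos + 1 :]
            if neighbour in STOP_CODONS:
                continue
            valid += 1
            if _translate(neighbour) == aa:
                syn += 1
        if valid:
            s += syn / valid
    return s


@lru_cache(maxsize=None)
def codon_pair_differences(codon_a: str, codon_b: str) -> tuple[float, float] | None:
    """Average (non-synonymous, synonymous) differences between two codons.

    Differences are averaged over all shortest single-nucleotide
    substitution paths between the codons, excluding any path that
    passes through (or ends in) a stop codon.  Returns ``None`` when
    every path is blocked by a stop.
    """
    if codon_a in STOP_CODONS or codon_b in STOP_CODONS:
        return None
    positions = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not positions:
        return (0.0, 0.0)
    nd_total = 0.0
    sd_total = 0.0
    n_paths = 0
    for order in permutations(positions):
        current = codon_a
        nd = sd = 0
        blocked = False
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if nxt in STOP_CODONS:
                blocked = True
                break
            if _translate(nxt) == _translate(current):
                sd += 1
            else:
                nd += 1
            current = nxt
        if blocked:
            continue
        nd_total += nd
        sd_total += sd
        n_paths += 1
    if n_paths == 0:
        return None
    return (nd_total / n_paths, sd_total / n_paths)


def jukes_cantor(p: float) -> float:
    """Jukes–Cantor correction d = -(3/4) ln(1 - 4p/3); NaN when p >= 3/4."""
    if p >= 0.75:
        return math.nan
    return -0.75 * math.log1p(-4.0 * p / 3.0)


@dataclass(frozen=True)
class NG86Result:
    dN: float
    dS: float
    N_sites: float
    S_sites: float
    codons_compared: int

    def __iter__(self):
        return iter((self.dN, self.dS, self.N_sites, self.S_sites))

    @property
    def omega(self) -> float:
        if math.isnan(self.dN) or math.isnan(self.dS) or self.dS == 0:
            return math.nan
        return self.dN / self.dS


def ng86_pair(seq_a: str, seq_b: str) -> NG86Result:
    """Nei–Gojobori dN and dS between two in-frame nucleotide sequences.

    Codons containing gaps or ambiguity codes in either sequence are
    skipped, as are codon pairs whose substitution paths are all
    blocked by stop codons.  Site counts are averaged over the two
    sequences; proportions receive the Jukes–Cantor correction, with
    NaN returned when the correction is undefined (p >= 3/4) or when no
    codons were compared.
    """
    if len(seq_a) != len(seq_b) or len(seq_a) % 3:
        raise FrameError(
            f"sequences must be equal length and divisible by 3 "
            f"(got {len(seq_a)} and {len(seq_b)})"
        )
    n_sites = s_sites = 0.0
    nd = sd = 0.0
    compared = 0
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i : i + 3], seq_b[i : i + 3]
        if not (set(ca) <= _BASES and set(cb) <= _BASES):
            continue
        if ca in STOP_CODONS or cb in STOP_CODONS:
            continue
        diffs = codon_pair_differences(ca, cb)
        if diffs is None:
            continue
        sa, sb = synonymous_sites(ca), synonymous_sites(cb)
        s_sites += (sa + sb) / 2.0
        n_sites += 3.0 - (sa + sb) / 2.0
        nd += diffs[0]
        sd += diffs[1]
        compared += 1
    if compared == 0:
        return NG86Result(math.nan, math.nan, math.nan, math.nan, 0)
    pn = nd / n_sites if n_sites > 0 else math.nan
    ps = sd / s_sites if s_sites > 0 else math.nan
    dn = jukes_cantor(pn) if not math.isnan(pn) else math.nan
    ds = jukes_cantor(ps) if not math.isnan(ps) else math.nan
    return NG86Result(dn, ds, n_sites, s_sites, compared)


@dataclass
class GeneDistanceMatrix:
    """Symmetric taxa × taxa distance matrix for one gene and metric.

    ``values`` holds NaN for missing entries; missingness is symmetric
    and the diagonal is zero before imputation.
    """

    gene_id: str
    taxa: tuple[str, ...]
    metric: str
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("matrix shape does not match taxa")
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValueError(f"asymmetric distance matrix for gene {self.gene_id}")
        object.__setattr__(self, "values", v)

    @property
    def n_missing(self) -> int:
        iu = np.triu_indices(len(self.taxa), k=1)
        return int(np.isnan(self.values[iu]).sum())


@dataclass
class DistanceTensor:
    """genes × taxa × taxa distances for one metric on a fixed panel."""

    metric: str
    taxa: tuple[str, ...]
    gene_ids: tuple[str, ...]
    values: np.ndarray  # (G, N, N), NaN = missing
    provenance: str = "computed"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        expected = (len(self.gene_ids), len(self.taxa), len(self.taxa))
        if v.shape != expected:
            raise ValueError(f"tensor shape {v.shape} != {expected}")
        self.values = v

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def gene_slice(self, gene_id: str) -> np.ndarray:
        return self.values[self.gene_ids.index(gene_id)]

    def copy(self) -> "DistanceTensor":
        return DistanceTensor(
            self.metric, self.taxa, self.gene_ids, self.values.copy(), self.provenance
        )


def hamming_matrix(
    alignment: CodonAlignment, min_shared_sites: int = 30
) -> GeneDistanceMatrix:
    """Pairwise p-distances over sites unambiguous in both taxa.

    For each taxon pair the distance is mismatches divided by compared
    sites, where compared sites carry an unambiguous base (A, C, G or T)
    in both sequences.  Pairs sharing fewer than ``min_shared_sites``
    such sites are recorded as missing.
    """
    n = alignment.n_taxa
    arrays = [np.frombuffer(s.encode(), dtype="S1") for s in alignment.sequences]
    bases = np.frombuffer(b"ACGT", dtype="S1")
    valid = [np.isin(a, bases) for a in arrays]
    values = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        both = valid[i] & valid[j]
        shared = int(both.sum())
        if shared < min_shared_sites:
            d = np.nan
        else:
            d = float((arrays[i][both] != arrays[j][both]).sum()) / shared
        values[i, j] = values[j, i] = d
    return GeneDistanceMatrix(alignment.gene_id, alignment.taxa, "hamming", values)


def ng86_matrices(
    alignment: CodonAlignment, min_shared_codons: int = 10
) -> tuple[GeneDistanceMatrix, GeneDistanceMatrix, GeneDistanceMatrix]:
    """Per-gene dN, dS and omega matrices from pairwise NG86 estimates.

    Pairs comparing fewer than ``min_shared_codons`` clean codons are
    missing; omega is missing wherever dS is zero or missing.
    """
    n = alignment.n_taxa
    dn = np.zeros((n, n))
    ds = np.zeros((n, n))
    omega = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        result = ng86_pair(alignment.sequences[i], alignment.sequences[j])
        if result.codons_compared < min_shared_codons:
            dn_ij = ds_ij = w_ij = np.nan
        else:
            dn_ij, ds_ij = result.dN, result.dS
            w_ij = result.omega
        dn[i, j] = dn[j, i] = dn_ij
        ds[i, j] = ds[j, i] = ds_ij
        omega[i, j] = omega[j, i] = w_ij
    taxa = alignment.taxa
    g = alignment.gene_id
    return (
        GeneDistanceMatrix(g, taxa, "dN", dn),
        GeneDistanceMatrix(g, taxa, "dS", ds),
        GeneDistanceMatrix(g, taxa, "omega", omega),
    )


def _panel_union(alignments: Iterable[CodonAlignment]) -> tuple[str, ...]:
    taxa: set[str] = set()
    for a in alignments:
        taxa.update(a.taxa)
    return tuple(sorted(taxa))


def build_distance_tensors(
    alignments: Sequence[CodonAlignment],
    metrics: Sequence[str] = ("hamming", "dN", "dS", "omega"),
    min_shared_sites: int = 30,
    min_shared_codons: int = 10,
    panel: Sequence[str] | None = None,
) -> tuple[dict[str, DistanceTensor], list[str]]:
    """Assemble per-metric tensors on the union taxon panel.

    Genes whose slice is entirely missing in any requested tensor are
    dropped from all tensors and returned in the second element as a
    log of genes with insufficient information.
    """
    if not alignments:
        raise EmptyPanel("no alignments provided")
    panel = tuple(panel) if panel is not None else _panel_union(alignments)
    index = {t: k for k, t in enumerate(panel)}
    n = len(panel)
    need_ng86 = any(m in ("dN", "dS", "omega") for m in metrics)
    per_gene: dict[str, dict[str, np.ndarray]] = {}
    for alignment in sorted(alignments, key=lambda a: a.gene_id):
        mats: dict[str, GeneDistanceMatrix] = {}
        if "hamming" in metrics:
            mats["hamming"] = hamming_matrix(alignment, min_shared_sites)
        if need_ng86:
            dn, ds, om = ng86_matrices(alignment, min_shared_codons)
            mats.update({"dN": dn, "dS": ds, "omega": om})
        slices: dict[str, np.ndarray] = {}
        for metric in metrics:
            full = np.full((n, n), np.nan)
            idx = np.array([index[t] for t in alignment.taxa])
            full[np.ix_(idx, idx)] = mats[metric].values
            # omega diagonal: 0/0 is not a distance; keep 0 where taxon present
            full[idx, idx] = 0.0
            slices[metric] = full
        per_gene[alignment.gene_id] = slices
    dropped = []
    kept: list[str] = []
    for gene_id, slices in per_gene.items():
        ok = True
        for metric in metrics:
            off = slices[metric][np.triu_indices(n, k=1)]
            if np.isnan(off).all():
                ok = False
        if ok:
            kept.append(gene_id)
        else:
            dropped.append(gene_id)
    if not kept:
        raise EmptyPanel("no genes survive tensor assembly")
    tensors = {}
    for metric in metrics:
        values = np.stack([per_gene[g][metric] for g in kept])
        tensors[metric] = DistanceTensor(metric, panel, tuple(kept), values)
    return tensors, dropped


class ParseError(ValueError):
    pass


class AsymmetryError(ValueError):
    pass


def _read_phylip_square(path: Path) -> tuple[list[str], np.ndarray]:
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not lines:
        raise ParseError(f"{path}: empty file")
    try:
        n = int(lines[0].split()[0])
    except ValueError as exc:
        raise ParseError(f"{path}:1: expected taxon count") from exc
    if len(lines) != n + 1:
        raise ParseError(f"{path}: expected {n} matrix rows, found {len(lines) - 1}")
    taxa = []
    values = np.zeros((n, n))
    for r, line in enumerate(lines[1:]):
        parts = line.split()
        if len(parts) != n + 1:
            raise ParseError(f"{path}:{r + 2}: expected {n + 1} fields")
        taxa.append(parts[0])
        for c, token in enumerate(parts[1:]):
            values[r, c] = np.nan if token.upper() in ("NA", "NAN") else float(token)
    return taxa, values


def import_distance_matrices(
    paths: Sequence[str | Path] | str | Path,
    format: str = "phylip",
    metric_tag: str = "imported",
    panel: Sequence[str] | None = None,
    strict: bool = False,
    atol: float = 1e-8,
) -> DistanceTensor:
    """Load externally computed per-gene distance matrices as a tensor.

    ``format`` is ``"phylip"`` (one square distance matrix per file,
    filename stem = gene id) or ``"long_tsv"`` (rows of gene_id,
    taxon_a, taxon_b, value; a single triangle suffices).  Matrices
    whose two triangles disagree by more than ``atol`` raise
    :class:`AsymmetryError` in strict mode and are otherwise averaged.
    """
    import pandas as pd

    if isinstance(paths, (str, Path)):
        paths = [paths]
    per_gene: dict[str, tuple[list[str], np.ndarray]] = {}
    if format == "phylip":
        for path in sorted(Path(p) for p in paths):
            per_gene[path.stem] = _read_phylip_square(path)
    elif format == "long_tsv":
        path = Path(paths if isinstance(paths, (str, Path)) else paths[0])
        frame = pd.read_csv(path, sep="\t", comment="#")
        required = {"gene_id", "taxon_a", "taxon_b", "value"}
        if not required <= set(frame.columns):
            raise ParseError(f"{path}: needs columns {sorted(required)}")
        for gene_id, sub in frame.groupby("gene_id", sort=True):
            taxa = sorted(set(sub["taxon_a"]) | set(sub["taxon_b"]))
            idx = {t: k for k, t in enumerate(taxa)}
            values = np.full((len(taxa), len(taxa)), np.nan)
            np.fill_diagonal(values, 0.0)
            for _, row in sub.iterrows():
                a, b = idx[row["taxon_a"]], idx[row["taxon_b"]]
                v = float(row["value"])
                existing = values[b, a]
                values[a, b] = v
                if np.isnan(existing) or a == b:
                    values[b, a] = v
                elif abs(existing - v) > atol:
                    if strict:
                        raise AsymmetryError(
                            f"{path}: gene {gene_id} pair "
                            f"({row['taxon_a']},{row['taxon_b']}) asymmetric"
                        )
                    values[a, b] = values[b, a] = (existing + v) / 2.0
            per_gene[str(gene_id)] = (taxa, values)
    else:
        raise ValueError(f"unknown format {format!r}")

    if not per_gene:
        raise EmptyPanel("no matrices imported")
    if panel is None:
        all_taxa: set[str] = set()
        for taxa, _ in per_gene.values():
            all_taxa.update(taxa)
        panel = tuple(sorted(all_taxa))
    else:
        panel = tuple(panel)
    index = {t: k for k, t in enumerate(panel)}
    n = len(panel)
    gene_ids = tuple(sorted(per_gene))
    values = np.full((len(gene_ids), n, n), np.nan)
    for g, gene_id in enumerate(gene_ids):
        taxa, mat = per_gene[gene_id]
        missing = [t for t in taxa if t not in index]
        if missing:
            raise ParseError(
                f"gene {gene_id}: taxa {missing} not in panel"
            )
        if not np.allclose(mat, mat.T, equal_nan=True, atol=atol):
            if strict:
                raise AsymmetryError(f"gene {gene_id}: asymmetric matrix")
            mat = (mat + mat.T) / 2.0
        idx = np.array([index[t] for t in taxa])
        values[g][np.ix_(idx, idx)] = mat
    return DistanceTensor(
        f"imported:{metric_tag}" if not metric_tag.startswith("imported") else metric_tag,
        panel,
        gene_ids,
        values,
        provenance="imported",
    )
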