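"""Synthetic data with implanted rate accelerations.

Every stage of the pipeline can be exercised against ground truth:
dated pure-birth trees, distance tensors in which a chosen fraction of
genes carries an omega acceleration confined to a focal clade, codon
alignments evolved by exact stochastic simulation, and a small on-disk
toy dataset with known preprocessing outcomes.

The tensor generator emulates the structure of real BUSCO panels:
per-gene rate multipliers (lognormal), multiplicative pairwise noise,
taxon-wise missingness (a taxon absent from a gene loses its whole
row and column), and clade-specific acceleration of the dN/dS ratio.
It does not emulate alignment error, paralogy, or codon-usage bias.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .alignments import CodonAlignment, STOP_CODONS, _FORWARD_TABLE
from .distances import DistanceTensor
from .summaries import DatedTree

__all__ = [
    "SimulationConfig",
    "TruthTable",
    "simulate_yule_tree",
    "simulate_tensor",
    "simulate_codon_alignment",
    "make_toy_dataset",
]

_NUCS = "ACGT"
_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
_SENSE = [
    a + b + c
    for a in _NUCS
    for b in _NUCS
    for c in _NUCS
    if a + b + c not in STOP_CODONS
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the tensor simulator.

    Defaults describe a mid-size BUSCO-style panel: a 16-taxon dated
    tree, 1000 genes of which 5% carry a five-fold dN/dS acceleration
    confined to pairwise paths within a focal clade, lognormal
    gene-rate spread of sigma 0.3, 10% multiplicative pairwise noise,
    and 5% taxon-per-gene missingness.
    """

    seed: int = 0
    n_taxa: int = 16
    n_genes: int = 1000
    rate_lognormal: tuple[float, float] = (0.0, 0.3)  # (mu, sigma) of rho_g
    noise_sigma: float = 0.1
    outlier_fraction: float = 0.05
    acceleration: float = 5.0
    focal_clade: tuple[str, ...] | None = None  # None = per-gene random clade
    missingness: float = 0.05
    accel_mode: str = "both"  # both | either endpoint in the focal clade
    omega0: float = 0.2
    ds_rate: float = 0.02  # synonymous distance per unit tree time
    birth_rate: float = 1.0
    # codon-simulator parameters
    n_codons: int = 300
    kappa: float = 2.0
    base_freqs: tuple[tuple[float, float, float, float], ...] | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.outlier_fraction < 1):
            raise ValueError("outlier_fraction must be in [0, 1)")
        if not (0 <= self.missingness < 1):
            raise ValueError("missingness must be in [0, 1)")
        if self.acceleration < 1:
            raise ValueError("acceleration must be at least 1")
        if self.accel_mode not in ("either", "both"):
            raise ValueError("accel_mode must be 'either' or 'both'")


@dataclass
class TruthTable:
    """Ground truth of one simulated tensor set.

    ``genes`` records per gene whether it carries an acceleration and,
    for accelerated genes, its focal clade (comma-joined labels).
    ``drivers`` records per (gene, taxon) pair whether the taxon lies
    in the gene's focal clade (``in_focal_clade``) and whether it is a
    genuine driver (in the clade and not removed by missingness).
    ``focal_clade`` is the clade shared by all outlier genes when one
    was fixed in the configuration, else None (per-gene clades).
    """

    genes: pd.DataFrame  # gene_id, is_outlier, focal_clade
    drivers: pd.DataFrame  # gene_id, taxon, in_focal_clade, is_driver
    focal_clade: tuple[str, ...] | None
    acceleration: float

    @property
    def outlier_gene_ids(self) -> set[str]:
        return set(self.genes.loc[self.genes["is_outlier"], "gene_id"])

    def driver_truth_pairs(self) -> set[tuple[str, str]]:
        flagged = self.drivers[self.drivers["is_driver"]]
        return {(g, t) for g, t in zip(flagged["gene_id"], flagged["taxon"])}


class _Lineage:
    __slots__ = ("start", "end", "children", "label")

    def __init__(self, start: float) -> None:
        self.start = start
        self.end: float | None = None
        self.children: list["_Lineage"] = []
        self.label: str | None = None


def simulate_yule_tree(
    n_taxa: int, birth_rate: float = 1.0, seed: int = 0
) -> DatedTree:
    """Pure-birth ultrametric tree with ``n_taxa`` extant tips.

    Starts from the root split (two lineages at time zero); each of k
    active lineages splits at rate ``birth_rate``, and the present is
    placed one further exponential waiting time after the last split,
    so all tip branches have positive length.  Reproducible: the same
    (n_taxa, birth_rate, seed) gives a byte-identical newick string.
    """
    if n_taxa < 2:
        raise ValueError("need at least two taxa")
    rng = np.random.default_rng(seed)
    t = 0.0
    root_children = [_Lineage(0.0), _Lineage(0.0)]
    active = list(root_children)
    while len(active) < n_taxa:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        idx = int(rng.integers(len(active)))
        parent = active.pop(idx)
        parent.end = t
        parent.children = [_Lineage(t), _Lineage(t)]
        active.extend(parent.children)
    t_end = t + rng.exponential(1.0 / (birth_rate * n_taxa))
    width = len(str(n_taxa))
    counter = [0]

    def finish(node: _Lineage) -> str:
        if not node.children:
            node.end = t_end
            counter[0] += 1
            node.label = f"T{counter[0]:0{width}d}"
            return f"{node.label}:{node.end - node.start:.10f}"
        parts = ",".join(finish(c) for c in node.children)
        return f"({parts}):{node.end - node.start:.10f}"

    newick = "(" + ",".join(finish(c) for c in root_children) + ");"
    return DatedTree.from_newick(newick)


def _candidate_clades(tree: DatedTree) -> list[tuple[str, ...]]:
    """Proper internal clades (2 <= size < N), in deterministic order."""
    n = len(tree.leaf_labels)
    clades = [
        tips for _, tips in tree.internal_nodes() if 2 <= len(tips) < n
    ]
    return sorted(clades)


def simulate_tensor(
    tree: DatedTree, config: SimulationConfig
) -> tuple[dict[str, DistanceTensor], TruthTable]:
    """Distance tensors (dS, dN, omega, hamming proxy) with ground truth.

    dS(g, a, b) = patristic(a, b) * ds_rate * rho_g * eps, with rho_g a
    lognormal per-gene rate multiplier and eps lognormal multiplicative
    pairwise noise.  dN carries the same systematic part times omega
    with an independent noise draw of the same sigma, so the observed
    omega = dN/dS is itself noisy — as it is when both distances are
    estimated from finite alignments.  Each outlier gene multiplies
    omega by ``acceleration`` for pairs with both (default) or either
    endpoint in its focal clade — "both" mirrors branch-specific
    acceleration, where only paths lying entirely inside the clade run
    on accelerated branches; when ``focal_clade`` is None every
    outlier gene draws its own clade uniformly from the tree's internal
    clades, emulating accelerations scattered across the phylogeny,
    otherwise the given clade is shared by all outlier genes.  The
    hamming proxy converts total substitution load per site back to an
    expected p-distance.  Missingness removes whole taxa from genes.
    """
    rng = np.random.default_rng(config.seed)
    panel = tree.leaf_labels
    n = len(panel)
    patristic = tree.patristic_matrix().loc[list(panel), list(panel)].to_numpy()
    fixed_clade: tuple[str, ...] | None = None
    if config.focal_clade is not None:
        fixed_clade = tuple(sorted(config.focal_clade))
        unknown = set(fixed_clade) - set(panel)
        if unknown:
            raise ValueError(f"focal clade taxa not in tree: {sorted(unknown)}")
        if not 0 < len(fixed_clade) < n:
            raise ValueError("focal clade must be a proper nonempty subset of taxa")
    clade_pool = _candidate_clades(tree)

    def pair_accel_mask(clade: tuple[str, ...]) -> np.ndarray:
        mask = np.array([t in clade for t in panel])
        if config.accel_mode == "either":
            accel = mask[:, None] | mask[None, :]
        else:
            accel = mask[:, None] & mask[None, :]
        np.fill_diagonal(accel, False)
        return accel

    g_count = config.n_genes
    width = len(str(g_count))
    gene_ids = tuple(f"g{k + 1:0{width}d}" for k in range(g_count))
    # acceleration of exactly 1 is a no-op: no gene is a genuine outlier
    effective_fraction = config.outlier_fraction if config.acceleration > 1 else 0.0
    n_outliers = int(round(effective_fraction * g_count))
    outlier_idx = rng.choice(g_count, size=n_outliers, replace=False)
    is_outlier = np.zeros(g_count, dtype=bool)
    is_outlier[outlier_idx] = True

    gene_clades: list[tuple[str, ...] | None] = []
    for g in range(g_count):
        if not is_outlier[g]:
            gene_clades.append(None)
        elif fixed_clade is not None:
            gene_clades.append(fixed_clade)
        else:
            gene_clades.append(clade_pool[int(rng.integers(len(clade_pool)))])

    mu, sigma = config.rate_lognormal
    rho = rng.lognormal(mu, sigma, size=g_count)
    iu = np.triu_indices(n, k=1)
    p_pairs = len(iu[0])

    shape = (g_count, n, n)
    ds = np.zeros(shape)
    dn = np.zeros(shape)
    omega = np.zeros(shape)
    hamming = np.zeros(shape)
    present = np.ones((g_count, n), dtype=bool)
    for g in range(g_count):
        eps_s = np.exp(rng.normal(0.0, config.noise_sigma, size=p_pairs))
        eps_n = np.exp(rng.normal(0.0, config.noise_sigma, size=p_pairs))
        base = patristic[iu] * config.ds_rate * rho[g]
        w = np.full(p_pairs, config.omega0)
        if gene_clades[g] is not None:
            w[pair_accel_mask(gene_clades[g])[iu]] *= config.acceleration
        ds_g = base * eps_s
        dn_g = w * base * eps_n
        for arr, vals in ((ds, ds_g), (dn, dn_g)):
            arr[g][iu] = vals
            arr[g][iu[1], iu[0]] = vals
        with np.errstate(divide="ignore", invalid="ignore"):
            w_obs = np.where(ds_g > 0, dn_g / ds_g, np.nan)
        omega[g][iu] = w_obs
        omega[g][iu[1], iu[0]] = w_obs
        # expected p-distance from the total per-site substitution load
        load = 0.75 * dn_g + 0.25 * ds_g
        h = 0.75 * (1.0 - np.exp(-4.0 * load / 3.0))
        hamming[g][iu] = h
        hamming[g][iu[1], iu[0]] = h
        if config.missingness > 0:
            drop = rng.random(n) < config.missingness
            if (~drop).sum() < 3:
                keep_idx = rng.choice(n, size=3, replace=False)
                drop = np.ones(n, dtype=bool)
                drop[keep_idx] = False
            present[g, drop] = False
            for arr in (ds, dn, omega, hamming):
                arr[g, drop, :] = np.nan
                arr[g, :, drop] = np.nan

    tensors = {
        metric: DistanceTensor(metric, panel, gene_ids, values)
        for metric, values in (
            ("dS", ds),
            ("dN", dn),
            ("omega", omega),
            ("hamming", hamming),
        )
    }
    genes = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "is_outlier": is_outlier,
            "focal_clade": [
                ",".join(c) if c is not None else "" for c in gene_clades
            ],
        }
    )
    driver_rows = []
    for g, gene_id in enumerate(gene_ids):
        clade = gene_clades[g] or ()
        for a, taxon in enumerate(panel):
            in_clade = taxon in clade
            driver_rows.append(
                {
                    "gene_id": gene_id,
                    "taxon": taxon,
                    "in_focal_clade": bool(in_clade),
                    "is_driver": bool(in_clade and present[g, a]),
                }
            )
    truth = TruthTable(
        genes=genes,
        drivers=pd.DataFrame(driver_rows),
        focal_clade=fixed_clade,
        acceleration=config.acceleration,
    )
    return tensors, truth


def _f3x4_codon_freqs(
    base_freqs: Sequence[Sequence[float]] | None,
) -> dict[str, float]:
    """Stationary sense-codon frequencies from position-wise base frequencies."""
    if base_freqs is None:
        base_freqs = [[0.25] * 4] * 3
    pos = [dict(zip(_NUCS, row)) for row in base_freqs]
    raw = {c: pos[0][c[0]] * pos[1][c[1]] * pos[2][c[2]] for c in _SENSE}
    total = sum(raw.values())
    return {c: v / total for c, v in raw.items()}


def _codon_moves(kappa: float, base_freqs) -> dict[str, list[tuple[str, float, bool]]]:
    """For each sense codon: (target, neutral_rate_factor, is_nonsynonymous)."""
    if base_freqs is None:
        base_freqs = [[0.25] * 4] * 3
    pos = [dict(zip(_NUCS, row)) for row in base_freqs]
    moves: dict[str, list[tuple[str, float, bool]]] = {}
    for codon in _SENSE:
        out = []
        for i in range(3):
            for base in _NUCS:
                if base == codon[i]:
                    continue
                target = codon[:i] + base + codon[i + 1 :]
                if target in STOP_CODONS:
                    continue
                rate = pos[i][base]
                if (codon[i], base) in _TRANSITIONS:
                    rate *= kappa
                nonsyn = _FORWARD_TABLE[target] != _FORWARD_TABLE[codon]
                out.append((target, rate, nonsyn))
        moves[codon] = out
    return moves


def simulate_codon_alignment(
    tree: DatedTree,
    n_codons: int,
    kappa: float = 2.0,
    omega: float = 0.2,
    base_freqs: Sequence[Sequence[float]] | None = None,
    seed: int = 0,
    gene_id: str = "sim",
    accel_clade: Sequence[str] | None = None,
    omega_accel: float | None = None,
    rate: float = 1.0,
) -> CodonAlignment:
    """Evolve codon sequences along a tree by exact stochastic simulation.

    Substitutions are proposed per codon with rate proportional to the
    target base frequency at that codon position, times kappa for
    transitions and omega for non-synonymous changes; stop codons are
    forbidden.  Branch lengths are read as expected substitutions per
    codon on the neutral scale (omega = 1 at the stationary codon
    distribution), after multiplication by ``rate`` (useful when the
    tree is in time units).  Branches whose descendant tips all lie
    inside ``accel_clade`` evolve under ``omega_accel`` instead of
    ``omega``.
    """
    rng = np.random.default_rng(seed)
    freqs = _f3x4_codon_freqs(base_freqs)
    moves = _codon_moves(kappa, base_freqs)
    # neutral mean substitution rate per codon at stationarity
    neutral_rate = sum(
        freqs[c] * sum(rate for _, rate, _ in moves[c]) for c in _SENSE
    )
    codons = list(freqs)
    probs = np.array([freqs[c] for c in codons])
    accel = set(accel_clade) if accel_clade else set()

    def branch_omega(node) -> float:
        if not accel or omega_accel is None:
            return omega
        tips = {l.taxon.label for l in node.leaf_iter()} if not node.is_leaf() else {
            node.taxon.label
        }
        return omega_accel if tips <= accel else omega

    def evolve(sequence: list[str], length: float, w: float) -> list[str]:
        duration = length / neutral_rate
        out = list(sequence)
        for k in range(len(out)):
            t = 0.0
            codon = out[k]
            while True:
                options = moves[codon]
                rates = [r * (w if nonsyn else 1.0) for _, r, nonsyn in options]
                total = sum(rates)
                t += rng.exponential(1.0 / total)
                if t >= duration:
                    break
                u = rng.random() * total
                acc = 0.0
                for (target, _, _), rate in zip(options, rates):
                    acc += rate
                    if u <= acc:
                        codon = target
                        break
            out[k] = codon
        return out

    root_seq = [codons[i] for i in rng.choice(len(codons), size=n_codons, p=probs)]
    sequences: dict[str, list[str]] = {}

    def walk(node, sequence: list[str]) -> None:
        for child in node.child_nodes():
            child_seq = evolve(
                sequence, (child.edge.length or 0.0) * rate, branch_omega(child)
            )
            if child.is_leaf():
                sequences[child.taxon.label] = child_seq
            else:
                walk(child, child_seq)

    walk(tree.tree.seed_node, root_seq)
    taxa = tuple(sorted(sequences))
    return CodonAlignment(
        gene_id=gene_id,
        taxa=taxa,
        sequences=tuple("".join(sequences[t]) for t in taxa),
        frame_offset=0,
    )


def make_toy_dataset(seed: int, out_dir: str | Path) -> pd.DataFrame:
    """Write the committed toy fixture: 12 genes over 10 taxa.

    Nine genes should pass preprocessing (two of them only after frame
    trimming, one after masking an internal stop, one after dropping a
    gappy codon column); one gene has too few taxa, one has no reading
    frame ending in stop codons, and one carries almost no variation.
    Returns the manifest of expected outcomes, which is also written as
    ``manifest.tsv`` next to the FASTA files, with the tree as
    ``tree.nwk``.  Regeneration with the same seed is byte-identical.
    """
    from .io import write_fasta  # local import to avoid a cycle

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tree = simulate_yule_tree(10, birth_rate=1.0, seed=seed)
    records = []

    def clean_alignment(gene_id: str, sub_seed: int) -> CodonAlignment:
        aln = simulate_codon_alignment(
            tree, n_codons=60, kappa=2.0, omega=0.2, seed=sub_seed,
            gene_id=gene_id, rate=0.15,
        )
        return replace(aln, sequences=tuple(s + "TAA" for s in aln.sequences))

    for k in range(1, 10):
        gene_id = f"g{k:02d}"
        aln = clean_alignment(gene_id, seed + 10 + k)
        seqs = list(aln.sequences)
        detail = "clean"
        if k == 2:  # shifted by one base
            seqs = ["G" + s for s in seqs]
            detail = "frame offset 1"
        elif k == 3:  # shifted by two bases
            seqs = ["GC" + s for s in seqs]
            detail = "frame offset 2"
        elif k == 4:  # internal stop in one taxon
            s = seqs[0]
            seqs[0] = s[:30] + "TGA" + s[33:]
            detail = "internal stop masked"
        elif k == 5:  # one codon column gapped in 6 of 10 taxa
            for t in range(6):
                s = seqs[t]
                seqs[t] = s[:45] + "---" + s[48:]
            detail = "gappy codon column removed"
        elif k == 6:  # ambiguity codes, below the heterozygosity threshold
            for t in range(3):
                s = seqs[t]
                seqs[t] = s[:60] + "R" + s[61:]
            detail = "ambiguity retained"
        records.append({"gene_id": gene_id, "expected": "accepted", "detail": detail})
        write_fasta(out / f"{gene_id}.fasta", aln.taxa, seqs)

    aln = clean_alignment("g10", seed + 30)
    write_fasta(out / "g10.fasta", aln.taxa[:8], list(aln.sequences[:8]))
    records.append({"gene_id": "g10", "expected": "too_few_taxa", "detail": "8 taxa"})

    aln = simulate_codon_alignment(
        tree, n_codons=60, kappa=2.0, omega=0.2, seed=seed + 31, gene_id="g11",
        rate=0.15,
    )
    seqs = [s[:-9] + "AAAAAAAAA" for s in aln.sequences]
    write_fasta(out / "g11.fasta", aln.taxa, seqs)
    records.append(
        {"gene_id": "g11", "expected": "no_frame_found", "detail": "no terminal stops"}
    )

    base = simulate_codon_alignment(
        tree, n_codons=60, kappa=2.0, omega=0.2, seed=seed + 32, gene_id="g12",
        rate=0.15,
    ).sequences[0]
    seqs = [base + "TAA" for _ in range(10)]
    write_fasta(out / "g12.fasta", aln.taxa, seqs)
    records.append(
        {"gene_id": "g12", "expected": "low_information", "detail": "invariant alignment"}
    )

    manifest = pd.DataFrame(records)
    manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
    (out / "tree.nwk").write_text(tree.to_newick() + "\n")
    return manifest
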