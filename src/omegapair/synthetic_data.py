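"""Synthetic genome-pair cohorts with known evolutionary parameters.

The generator produces exactly the statistical structure the analysis
pipeline assumes, so that every stage has a recoverable ground truth:

* genes evolve under a GY94-style codon substitution model — a reversible
  61-state Markov chain with rate ``pi_j * kappa^[transition] *
  omega^[nonsynonymous]`` for single-nucleotide codon changes, scaled so
  one unit of branch length equals one expected substitution per codon at
  stationarity;
* a genome pair diverges symmetrically from a common ancestor (t/2 per
  branch, pairwise distance t), with no indels, gene gain/loss or
  rearrangement, so the true ortholog pairing is the identity map;
* genes are wrapped with ATG/TAA and laid on a single contig separated by
  noncoding spacers sized to a requested noncoding fraction; spacers
  descend from common ancestral sequence under Jukes-Cantor at the same
  per-site divergence as the coding average, so fragment ANI is uniform
  across the genome;
* cohorts inject the two regimes under study: an "archaeal-like" regime
  where true omega rises and noncoding fraction rises with genome size,
  and a "bacterial-like" regime where omega falls with size and the
  noncoding fraction is size-independent.

All randomness flows from one explicitly passed seed; identical
configuration and seed give byte-identical FASTA/GFF3 output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.linalg import expm

from .codon_evolution import code_tables
from .genome_model import CdsFeature, GenomeRecord, translate_cds, write_genome

_NUCS = "ACGT"
_TRANSITION = np.array(
    [[0, 0, 1, 0], [0, 0, 0, 1], [1, 0, 0, 0], [0, 1, 0, 0]], dtype=bool
)  # A<->G, C<->T

START_CODON = "ATG"
STOP_CODON = "TAA"


@dataclass
class SimConfig:
    """Parameters of one simulated genome pair.

    ``t`` is the pairwise branch length in expected substitutions per codon;
    ``gene_len_codons`` is a fixed count or an inclusive (lo, hi) sampling
    range for the gene body (start/stop codons are added on top);
    ``codon_freqs`` is ``"uniform"`` or an explicit length-61 distribution
    over sense codons.
    """

    n_genes: int = 100
    gene_len_codons: int | tuple[int, int] = 300
    omega: float = 0.2
    kappa: float = 2.0
    t: float = 0.3
    codon_freqs: str | np.ndarray = "uniform"
    noncoding_fraction: float = 0.2
    seed: int = 0
    table_id: int = 11
    genome_id_a: str = "sim_A"
    genome_id_b: str = "sim_B"


@dataclass
class SimTruth:
    """The hidden parameters behind one simulated pair (recovery tests)."""

    omega: float
    kappa: float
    t: float
    noncoding_fraction_requested: float
    noncoding_fraction_realized: float
    n_genes: int
    size_bp_a: int
    size_bp_b: int
    ortholog_pairs: list[tuple[str, str]] = field(default_factory=list)
    seed: int = 0


def resolve_codon_freqs(
    codon_freqs: str | np.ndarray, table_id: int = 11
) -> np.ndarray:
    tables = code_tables(table_id)
    n = len(tables.sense_codons)
    if isinstance(codon_freqs, str):
        if codon_freqs != "uniform":
            raise ValueError(f"unknown codon_freqs value {codon_freqs!r}")
        return np.full(n, 1.0 / n)
    pi = np.asarray(codon_freqs, dtype=float)
    if pi.shape != (n,) or not np.isclose(pi.sum(), 1.0):
        raise ValueError(f"codon_freqs must be a length-{n} distribution")
    return pi


def f3x4_codon_freqs(nuc_freqs, table_id: int = 11) -> np.ndarray:
    """Build an F3x4 sense-codon distribution from position-specific
    nucleotide frequencies (shape (3, 4), order ACGT)."""
    f = np.asarray(nuc_freqs, dtype=float)
    if f.shape == (4,):
        f = np.tile(f, (3, 1))
    if f.shape != (3, 4):
        raise ValueError("nuc_freqs must have shape (4,) or (3, 4)")
    f = f / f.sum(axis=1, keepdims=True)
    tables = code_tables(table_id)
    idx = {n: i for i, n in enumerate(_NUCS)}
    pi = np.array(
        [f[0, idx[c[0]]] * f[1, idx[c[1]]] * f[2, idx[c[2]]]
         for c in tables.sense_codons]
    )
    if (pi <= 0).any():
        raise ValueError("F3x4 frequencies put zero mass on a sense codon")
    return pi / pi.sum()


def build_codon_rate_matrix(
    kappa: float,
    omega: float,
    codon_freqs: str | np.ndarray = "uniform",
    table_id: int = 11,
) -> np.ndarray:
    """GY94 rate matrix over sense codons, scaled to 1 substitution/codon/t.

    Entry (i, j) is nonzero only for single-nucleotide codon changes and
    equals ``pi_j * kappa^[transition] * omega^[nonsynonymous]``; rows sum
    to zero and the whole matrix is rescaled so the expected substitution
    rate at stationarity is one per codon per unit branch length.  The
    chain satisfies detailed balance by construction.
    """
    tables = code_tables(table_id)
    pi = resolve_codon_freqs(codon_freqs, table_id)
    if (pi <= 0).any():
        raise ValueError("codon frequencies must be strictly positive")
    n = len(tables.sense_codons)
    Q = np.zeros((n, n))
    rates = pi[tables.nb_to] * np.where(tables.nb_ts, kappa, 1.0)
    rates = rates * np.where(tables.nb_syn, 1.0, omega)
    np.add.at(Q, (tables.nb_from, tables.nb_to), rates)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    scale = -(pi * np.diag(Q)).sum()
    if scale <= 0:
        raise ValueError("degenerate rate matrix (zero total rate)")
    return Q / scale


def transition_kernel(Q: np.ndarray, t: float) -> np.ndarray:
    """P(t) = expm(Q t), cleaned to a proper stochastic matrix."""
    P = expm(Q * t)
    P = np.clip(P, 0.0, None)
    return P / P.sum(axis=1, keepdims=True)


def evolve_codon_sequence(
    ancestor: np.ndarray,
    t: float,
    matrix: np.ndarray,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Evolve codon indices for time t under rate matrix ``matrix``.

    Sites are independent; each codon is drawn from its row of the
    transition kernel.  Deterministic given the seed.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    ancestor = np.asarray(ancestor)
    if t == 0:
        return ancestor.copy()
    P = transition_kernel(matrix, t)
    out = np.empty_like(ancestor)
    for codon in np.unique(ancestor):
        mask = ancestor == codon
        out[mask] = rng.choice(len(P), size=int(mask.sum()), p=P[codon])
    return out


def _jc_diverge(seq: np.ndarray, d: float, rng: np.random.Generator) -> np.ndarray:
    """Evolve nucleotide indices by Jukes-Cantor for distance d (subs/site)."""
    p_change = 0.75 * (1.0 - np.exp(-4.0 * d / 3.0))
    hit = rng.random(len(seq)) < p_change
    shifts = rng.integers(1, 4, size=int(hit.sum()))
    out = seq.copy()
    out[hit] = (out[hit] + shifts) % 4
    return out


def _indices_to_nt(idx: np.ndarray) -> str:
    return "".join(_NUCS[i] for i in idx)


def _codons_to_nt(codon_idx: np.ndarray, tables) -> str:
    return "".join(tables.sense_codons[i] for i in codon_idx)


def simulate_genome_pair(
    config: SimConfig,
) -> tuple[GenomeRecord, GenomeRecord, SimTruth]:
    """One genome pair diverged under the configured codon model."""
    tables = code_tables(config.table_id)
    rng = np.random.default_rng(config.seed)
    pi = resolve_codon_freqs(config.codon_freqs, config.table_id)
    Q = build_codon_rate_matrix(
        config.kappa, config.omega, pi, config.table_id
    )

    if isinstance(config.gene_len_codons, tuple):
        lo, hi = config.gene_len_codons
        lens = rng.integers(lo, hi + 1, size=config.n_genes)
    else:
        lens = np.full(config.n_genes, int(config.gene_len_codons))
    bounds = np.concatenate([[0], np.cumsum(lens)])
    ancestor = rng.choice(len(pi), size=int(bounds[-1]), p=pi)
    # evolve all gene bodies at once; split per gene afterwards
    desc_a = evolve_codon_sequence(ancestor, config.t / 2.0, Q, rng)
    desc_b = evolve_codon_sequence(ancestor, config.t / 2.0, Q, rng)

    coding_bp = int((lens + 2).sum()) * 3
    if not 0 <= config.noncoding_fraction < 1:
        raise ValueError("noncoding_fraction must lie in [0, 1)")
    noncoding_bp = int(round(
        coding_bp * config.noncoding_fraction / (1.0 - config.noncoding_fraction)
    ))
    n_spacers = config.n_genes + 1
    spacer_lens = rng.multinomial(noncoding_bp, np.full(n_spacers, 1.0 / n_spacers))
    d_nc = config.t / 3.0  # coding-average per-site divergence
    spacers_a, spacers_b = [], []
    for sl in spacer_lens:
        anc = rng.integers(0, 4, size=int(sl))
        spacers_a.append(_indices_to_nt(_jc_diverge(anc, d_nc / 2.0, rng)))
        spacers_b.append(_indices_to_nt(_jc_diverge(anc, d_nc / 2.0, rng)))

    def _assemble(desc, spacers, genome_id):
        parts, feats = [], []
        pos = 0
        for g in range(config.n_genes):
            parts.append(spacers[g])
            pos += len(spacers[g])
            body = _codons_to_nt(desc[bounds[g] : bounds[g + 1]], tables)
            cds = START_CODON + body + STOP_CODON
            start = pos + 1
            end = pos + len(cds)
            feats.append(
                CdsFeature(
                    gene_id=f"g{g + 1:05d}",
                    contig_id="chr1",
                    start=start,
                    end=end,
                    strand="+",
                    nt_seq=cds,
                    aa_seq=translate_cds(cds, table=config.table_id)[:-1],
                )
            )
            parts.append(cds)
            pos = end
        parts.append(spacers[-1])
        seq = "".join(parts)
        return GenomeRecord(
            genome_id=genome_id, contigs=[("chr1", seq)], cds_list=feats
        )

    rec_a = _assemble(desc_a, spacers_a, config.genome_id_a)
    rec_b = _assemble(desc_b, spacers_b, config.genome_id_b)
    realized = noncoding_bp / (noncoding_bp + coding_bp)
    truth = SimTruth(
        omega=config.omega,
        kappa=config.kappa,
        t=config.t,
        noncoding_fraction_requested=config.noncoding_fraction,
        noncoding_fraction_realized=realized,
        n_genes=config.n_genes,
        size_bp_a=rec_a.size_bp(),
        size_bp_b=rec_b.size_bp(),
        ortholog_pairs=[(f.gene_id, f.gene_id) for f in rec_a.cds_list],
        seed=config.seed,
    )
    return rec_a, rec_b, truth


# ---------------------------------------------------------------------------
# cohorts

# Desk-scale study conditions: gene counts span a threefold size range, gene
# bodies 150-250 codons, and pairwise distances drawn so computed ANI falls
# mostly inside the 75-95% congeneric window.  True omega spans 0.05-0.20
# (the empirical range of prokaryotic genome-pair means) and is tied to
# genome size with the direction of the regime.
COHORT_GENES_MIN = 60
COHORT_GENES_MAX = 180
COHORT_GENE_LEN = (150, 250)
COHORT_T_RANGE = (0.25, 0.55)
COHORT_OMEGA_RANGE = (0.05, 0.20)
ARCHAEAL_NONCODING_RANGE = (0.08, 0.30)
BACTERIAL_NONCODING_MEAN = 0.12
BACTERIAL_NONCODING_JITTER = 0.03

REGIMES = ("archaeal-like", "bacterial-like")


def simulate_cohort(
    regime: str,
    n_pairs: int,
    seed: int,
    outdir: str | Path | None = None,
    kappa: float = 2.0,
) -> tuple[
    pd.DataFrame, list[tuple[GenomeRecord, GenomeRecord]], list[SimTruth]
]:
    """A cohort of genome pairs realising one regime's size associations.

    Archaeal-like: true omega and the noncoding fraction both increase
    with genome size.  Bacterial-like: true omega decreases with size and
    the noncoding fraction is flat in size (small independent jitter).
    Returns ``(manifest, pairs, truths)``; with ``outdir`` the genomes,
    manifest TSV and a truth JSON are also written to disk.
    """
    if regime not in REGIMES:
        raise ValueError(f"regime must be one of {REGIMES}")
    if n_pairs < 5:
        raise ValueError("a cohort needs at least 5 pairs")
    rng = np.random.default_rng(seed)
    children = np.random.SeedSequence(seed).spawn(n_pairs)
    # evenly spread sizes, shuffled so size is not confounded with pair id
    u = np.linspace(0.0, 1.0, n_pairs)
    rng.shuffle(u)
    o_lo, o_hi = COHORT_OMEGA_RANGE
    rows, pairs, truths = [], [], []
    for i in range(n_pairs):
        if regime == "archaeal-like":
            omega = o_lo + u[i] * (o_hi - o_lo)
            nc_lo, nc_hi = ARCHAEAL_NONCODING_RANGE
            noncoding = nc_lo + u[i] * (nc_hi - nc_lo)
        else:
            omega = o_hi - u[i] * (o_hi - o_lo)
            noncoding = BACTERIAL_NONCODING_MEAN + rng.uniform(
                -BACTERIAL_NONCODING_JITTER, BACTERIAL_NONCODING_JITTER
            )
        n_genes = int(round(
            COHORT_GENES_MIN + u[i] * (COHORT_GENES_MAX - COHORT_GENES_MIN)
        ))
        t = rng.uniform(*COHORT_T_RANGE)
        pair_id = f"pair_{i + 1:03d}"
        cfg = SimConfig(
            n_genes=n_genes,
            gene_len_codons=COHORT_GENE_LEN,
            omega=float(omega),
            kappa=kappa,
            t=float(t),
            noncoding_fraction=float(noncoding),
            seed=int(children[i].generate_state(1)[0] % (2**31)),
            genome_id_a=f"{pair_id}_A",
            genome_id_b=f"{pair_id}_B",
        )
        rec_a, rec_b, truth = simulate_genome_pair(cfg)
        pairs.append((rec_a, rec_b))
        truths.append(truth)
        rows.append(
            {
                "pair_id": pair_id,
                "regime": regime,
                "fasta_a": f"{pair_id}_A.fna",
                "gff_a": f"{pair_id}_A.gff3",
                "fasta_b": f"{pair_id}_B.fna",
                "gff_b": f"{pair_id}_B.gff3",
            }
        )
    manifest = pd.DataFrame(rows)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for row, (rec_a, rec_b) in zip(rows, pairs):
            write_genome(rec_a, outdir / row["fasta_a"], outdir / row["gff_a"])
            write_genome(rec_b, outdir / row["fasta_b"], outdir / row["gff_b"])
        manifest.to_csv(outdir / "manifest.tsv", sep="\t", index=False)
        with open(outdir / "truth.json", "w") as fh:
            json.dump([asdict(t) for t in truths], fh, indent=1)
    return manifest, pairs, truths
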