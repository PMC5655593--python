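"""Codon-level divergence estimation: NG86 and YN00 dN/dS, saturation
filters, and per-genome-pair summaries.

The unit of analysis is a pair of orthologous coding sequences.  A protein
alignment is back-threaded onto the two CDS to give a codon alignment;
synonymous and nonsynonymous sites and differences are then counted with
either of two classical counting methods:

* **NG86** (Nei & Gojobori 1986): each codon position contributes its
  synonymous fraction among single-nucleotide changes (mutations to stop
  codons excluded from the denominator); observed codon differences are
  averaged over all orderings of the single-step mutational pathways, and
  the raw proportions are corrected for multiple hits with the
  Jukes-Cantor formula.  NG86 assumes no transition/transversion bias and
  equal codon usage; it is simple enough to verify exhaustively, and serves
  as the always-available baseline.

* **YN00** (after Yang & Nielsen 2000): the same counting skeleton, but
  site and pathway weights incorporate a transition/transversion ratio
  kappa (estimated from fourfold-degenerate and nondegenerate sites with
  the Kimura two-parameter model) and codon frequencies (F3x4, estimated
  from the sequence pair); transition and transversion differences are
  corrected separately with the K80 distance, and omega is updated
  iteratively because pathway weights depend on it.  With kappa = 1 and
  uniform codon frequencies the weights collapse and the site counts reduce
  exactly to NG86's.

Estimates whose synonymous distance is too small (dS < 0.1: near-zero
divergence, ratio unstable), too large (dS > 1.6: saturated), or whose
ratio explodes (dN/dS > 99) are discarded before per-pair averaging, and a
genome pair is only kept when the surviving orthologs cover at least 5% of
the pair's average coding capacity.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from Bio.Data import CodonTable

from .orthology import ProteinAlignment

logger = logging.getLogger(__name__)

OMEGA_SENTINEL = 999.0  # emitted when dS = 0; always caught by the >99 filter
DS_MIN = 0.1
DS_MAX = 1.6
OMEGA_MAX = 99.0
RETENTION_FRACTION = 0.05

_NUCS = "ACGT"
_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


class CodonError(ValueError):
    """A codon is not a sense codon under the genetic code in use."""


# ---------------------------------------------------------------------------
# genetic-code tables (built once per code table id)

class _CodeTables:
    """Precomputed sense-codon machinery for one genetic code."""

    def __init__(self, table_id: int):
        code = CodonTable.unambiguous_dna_by_id[table_id]
        self.table_id = table_id
        self.stop_codons = set(code.stop_codons)
        self.sense_codons = sorted(
            c for c in code.forward_table if set(c) <= set(_NUCS)
        )
        self.index = {c: i for i, c in enumerate(self.sense_codons)}
        self.aa = [code.forward_table[c] for c in self.sense_codons]
        n = len(self.sense_codons)

        # single-nucleotide neighbours of every sense codon
        # flat arrays for vectorised YN00 site counting
        nb_from, nb_to, nb_ts, nb_syn, nb_pos = [], [], [], [], []
        s_sites = np.zeros(n)
        for i, codon in enumerate(self.sense_codons):
            per_pos_syn = 0.0
            for pos in range(3):
                syn = nonstop = 0
                for nuc in _NUCS:
                    if nuc == codon[pos]:
                        continue
                    alt = codon[:pos] + nuc + codon[pos + 1 :]
                    if alt in self.stop_codons:
                        continue
                    nonstop += 1
                    j = self.index[alt]
                    is_syn = self.aa[j] == self.aa[i]
                    syn += is_syn
                    nb_from.append(i)
                    nb_to.append(j)
                    nb_ts.append((codon[pos], nuc) in _TRANSITIONS)
                    nb_syn.append(is_syn)
                    nb_pos.append(pos)
                per_pos_syn += syn / nonstop if nonstop else 0.0
            s_sites[i] = per_pos_syn
        self.nb_from = np.array(nb_from)
        self.nb_to = np.array(nb_to)
        self.nb_ts = np.array(nb_ts, dtype=bool)
        self.nb_syn = np.array(nb_syn, dtype=bool)
        self.nb_pos = np.array(nb_pos)
        self.s_sites = s_sites  # NG86 synonymous sites per codon (n = 3 - s)

        # degeneracy class of each (codon, position): 4 if every non-stop
        # change is synonymous (and none hits a stop), 0 if none is
        self.degeneracy = np.full((n, 3), -1, dtype=int)
        for i, codon in enumerate(self.sense_codons):
            for pos in range(3):
                syn = nonstop = 0
                for nuc in _NUCS:
                    if nuc == codon[pos]:
                        continue
                    alt = codon[:pos] + nuc + codon[pos + 1 :]
                    if alt in self.stop_codons:
                        continue
                    nonstop += 1
                    syn += self.aa[self.index[alt]] == self.aa[i]
                if syn == 0:
                    self.degeneracy[i, pos] = 0
                elif syn == 3 and nonstop == 3:
                    self.degeneracy[i, pos] = 4

        self._pathways: dict[tuple[int, int], list | None] = {}
        self._ng86_diff: dict[tuple[int, int], tuple[float, float]] = {}

    # -- mutational pathways between two codons --------------------------

    def pathways(self, i: int, j: int):
        """All stop-free single-step pathways from codon i to codon j.

        Returns a list of pathways, each a list of steps
        ``(target_idx, is_ts, is_syn)``; ``None`` when every ordering of
        the changes passes through a stop codon (degenerate case).
        Cached per unordered orientation is NOT used: the step targets
        depend on direction, so the cache key is the ordered pair.
        """
        key = (i, j)
        if key in self._pathways:
            return self._pathways[key]
        a, b = self.sense_codons[i], self.sense_codons[j]
        diff_pos = [p for p in range(3) if a[p] != b[p]]
        paths = []
        for order in itertools.permutations(diff_pos):
            cur = a
            steps = []
            dead = False
            for pos in order:
                nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
                if nxt in self.stop_codons:
                    dead = True
                    break
                tgt = self.index[nxt]
                steps.append(
                    (
                        tgt,
                        (cur[pos], b[pos]) in _TRANSITIONS,
                        self.aa[tgt] == self.aa[self.index[cur]],
                        pos,
                    )
                )
                cur = nxt
            if not dead:
                paths.append(steps)
        result = paths if paths else None
        self._pathways[key] = result
        return result

    def ng86_diff(self, i: int, j: int) -> tuple[float, float]:
        """(sd, nd) averaged with equal weight over surviving pathways."""
        if i == j:
            return (0.0, 0.0)
        key = (min(i, j), max(i, j))
        if key in self._ng86_diff:
            return self._ng86_diff[key]
        paths = self.pathways(*key)
        k = sum(
            1
            for p in range(3)
            if self.sense_codons[i][p] != self.sense_codons[j][p]
        )
        if paths is None:
            logger.warning(
                "all mutational pathways %s->%s pass through stops; "
                "splitting %d differences equally",
                self.sense_codons[i],
                self.sense_codons[j],
                k,
            )
            out = (k / 2.0, k / 2.0)
        else:
            sd = sum(sum(st[2] for st in path) for path in paths) / len(paths)
            out = (sd, k - sd)
        self._ng86_diff[key] = out
        return out


_TABLES: dict[int, _CodeTables] = {}


def code_tables(table_id: int = 11) -> _CodeTables:
    if table_id not in _TABLES:
        _TABLES[table_id] = _CodeTables(table_id)
    return _TABLES[table_id]


# ---------------------------------------------------------------------------
# data containers


@dataclass
class CodonAlignment:
    """Gap-free, unambiguous codon columns of one ortholog pair."""

    gene_a: str
    gene_b: str
    codon_columns: list[tuple[str, str]]
    n_columns_removed: int = 0
    table_id: int = 11


@dataclass
class DnDsEstimate:
    """Synonymous/nonsynonymous sites, differences and rates for one pair.

    ``omega`` is ``dN/dS``; when ``dS`` is exactly zero it carries the
    sentinel 999 so the downstream ">99" filter disposes of it uniformly.
    Saturated Jukes-Cantor/K80 corrections (p beyond the formula's domain)
    yield infinite distances rather than errors, again for uniform
    filtering.
    """

    gene_a: str
    gene_b: str
    method: str
    S: float
    N: float
    Sd: float
    Nd: float
    dS: float
    dN: float
    omega: float
    kappa: float = 1.0
    converged: bool = True
    n_codons: int = 0


@dataclass
class GenomePairSummary:
    """One genome pair's retained-ortholog dN/dS summary (one output row)."""

    genome_a: str
    genome_b: str
    n_orthologs: int
    n_retained: int
    mean_omega: float | None
    sem_omega: float | None
    retained_fraction_of_capacity: float
    keep: bool
    ani_pct: float | None
    size_a_cds: int
    size_b_cds: int
    size_a_bp: int = 0
    size_b_bp: int = 0
    coding_density_a: float | None = None
    coding_density_b: float | None = None
    discard_reasons: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# codon alignment construction


def backthread_codon_alignment(
    alignment: ProteinAlignment,
    cds_a: str,
    cds_b: str,
    table_id: int = 11,
) -> CodonAlignment:
    """Thread a protein alignment back onto its two coding sequences.

    Every aligned residue column maps to the source codons; columns with a
    gap, an ambiguous (non-ACGT) codon, or a stop codon are dropped and
    counted in ``n_columns_removed``.  A terminal stop codon on either CDS
    is ignored.
    """
    from .genome_model import translate_cds

    tables = code_tables(table_id)

    def _strip_stop(cds: str, gene: str) -> str:
        if len(cds) % 3 != 0:
            raise CodonError(f"{gene}: CDS length {len(cds)} not divisible by 3")
        if cds[-3:].upper() in tables.stop_codons:
            return cds[:-3]
        return cds

    cds_a = _strip_stop(cds_a.upper(), alignment.query_id)
    cds_b = _strip_stop(cds_b.upper(), alignment.subject_id)
    for gene, cds, gapped in (
        (alignment.query_id, cds_a, alignment.aligned_query),
        (alignment.subject_id, cds_b, alignment.aligned_subject),
    ):
        aa = gapped.replace("-", "")
        if translate_cds(cds, table=tables.table_id) != aa:
            raise CodonError(
                f"{gene}: CDS translation does not match aligned protein"
            )

    cols: list[tuple[str, str]] = []
    removed = 0
    ia = ib = 0
    for ra, rb in zip(alignment.aligned_query, alignment.aligned_subject):
        codon_a = cds_a[3 * ia : 3 * ia + 3] if ra != "-" else None
        codon_b = cds_b[3 * ib : 3 * ib + 3] if rb != "-" else None
        ia += ra != "-"
        ib += rb != "-"
        if codon_a is None or codon_b is None:
            removed += 1
            continue
        if codon_a in tables.index and codon_b in tables.index:
            cols.append((codon_a, codon_b))
        else:
            removed += 1
    return CodonAlignment(
        gene_a=alignment.query_id,
        gene_b=alignment.subject_id,
        codon_columns=cols,
        n_columns_removed=removed,
        table_id=table_id,
    )


# ---------------------------------------------------------------------------
# NG86


def ng86_count_sites(codon: str, table_id: int = 11) -> tuple[float, float]:
    """Synonymous/nonsynonymous site counts of one sense codon (s + n = 3)."""
    tables = code_tables(table_id)
    codon = codon.upper()
    if codon not in tables.index:
        raise CodonError(f"not a sense codon: {codon!r}")
    s = float(tables.s_sites[tables.index[codon]])
    return s, 3.0 - s


def ng86_count_differences(
    codon_a: str, codon_b: str, table_id: int = 11
) -> tuple[float, float]:
    """Pathway-averaged synonymous/nonsynonymous difference counts."""
    tables = code_tables(table_id)
    codon_a, codon_b = codon_a.upper(), codon_b.upper()
    for c in (codon_a, codon_b):
        if c not in tables.index:
            raise CodonError(f"not a sense codon: {c!r}")
    return tables.ng86_diff(tables.index[codon_a], tables.index[codon_b])


def jukes_cantor(p: float) -> float:
    """JC69 multiple-hit correction; infinite once p reaches the 3/4 ceiling."""
    if p < 0:
        raise ValueError("proportion must be >= 0")
    if p >= 0.75:
        return math.inf
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def _finish_estimate(
    gene_a, gene_b, method, S, N, Sd, Nd, dS, dN, kappa, converged, n_codons
) -> DnDsEstimate:
    if dS == 0.0:
        omega = OMEGA_SENTINEL
    elif math.isinf(dS):
        omega = 0.0 if math.isfinite(dN) else OMEGA_SENTINEL
    else:
        omega = dN / dS
    return DnDsEstimate(
        gene_a=gene_a,
        gene_b=gene_b,
        method=method,
        S=S,
        N=N,
        Sd=Sd,
        Nd=Nd,
        dS=dS,
        dN=dN,
        omega=omega,
        kappa=kappa,
        converged=converged,
        n_codons=n_codons,
    )


def _column_indices(ca: CodonAlignment) -> tuple[np.ndarray, np.ndarray]:
    tables = code_tables(ca.table_id)
    ia = np.array([tables.index[a] for a, _ in ca.codon_columns])
    ib = np.array([tables.index[b] for _, b in ca.codon_columns])
    return ia, ib


def ng86_estimate(ca: CodonAlignment) -> DnDsEstimate:
    """NG86 dN/dS for one codon alignment (Jukes-Cantor corrected)."""
    if not ca.codon_columns:
        raise ValueError(f"{ca.gene_a}/{ca.gene_b}: empty codon alignment")
    tables = code_tables(ca.table_id)
    ia, ib = _column_indices(ca)
    S = 0.5 * (tables.s_sites[ia].sum() + tables.s_sites[ib].sum())
    N = 3.0 * len(ca.codon_columns) - S
    Sd = Nd = 0.0
    for i, j in zip(ia, ib):
        if i != j:
            sd, nd = tables.ng86_diff(int(i), int(j))
            Sd += sd
            Nd += nd
    dS = jukes_cantor(Sd / S) if S > 0 else 0.0
    dN = jukes_cantor(Nd / N) if N > 0 else 0.0
    return _finish_estimate(
        ca.gene_a, ca.gene_b, "NG86", S, N, Sd, Nd, dS, dN, 1.0, True,
        len(ca.codon_columns),
    )


# ---------------------------------------------------------------------------
# YN00


def _k80_distance(P: float, Q: float) -> tuple[float, float, float]:
    """K80 distance and its transition/transversion components.

    Returns ``(d, alpha_t, beta_t)``; components are ``inf`` when the
    observed proportions are outside the formula's domain (saturation).
    """
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        return math.inf, math.inf, math.inf
    alpha_t = -0.5 * math.log(w1) + 0.25 * math.log(w2)
    beta_t = -0.25 * math.log(w2)
    return alpha_t + 2.0 * beta_t, alpha_t, beta_t


def f3x4_frequencies(ca: CodonAlignment, pseudocount: float = 0.5) -> np.ndarray:
    """F3x4 codon frequencies over sense codons, estimated from both rows."""
    tables = code_tables(ca.table_id)
    counts = np.full((3, 4), pseudocount)
    nuc_idx = {n: i for i, n in enumerate(_NUCS)}
    for a, b in ca.codon_columns:
        for codon in (a, b):
            for pos in range(3):
                counts[pos, nuc_idx[codon[pos]]] += 1
    fpos = counts / counts.sum(axis=1, keepdims=True)
    pi = np.array(
        [
            fpos[0, nuc_idx[c[0]]] * fpos[1, nuc_idx[c[1]]] * fpos[2, nuc_idx[c[2]]]
            for c in tables.sense_codons
        ]
    )
    return pi / pi.sum()


def estimate_kappa(ca: CodonAlignment) -> float:
    """Transition/transversion rate ratio from fourfold-degenerate and
    nondegenerate sites, via the K80 model, weighted by site counts."""
    tables = code_tables(ca.table_id)
    ia, ib = _column_indices(ca)
    L = {0: 0.0, 4: 0.0}
    ts = {0: 0.0, 4: 0.0}
    tv = {0: 0.0, 4: 0.0}
    for i, j in zip(ia, ib):
        ca_str = tables.sense_codons[i]
        cb_str = tables.sense_codons[j]
        for pos in range(3):
            da = tables.degeneracy[i, pos]
            db = tables.degeneracy[j, pos]
            if da != db or da not in (0, 4):
                continue
            L[da] += 1
            if ca_str[pos] != cb_str[pos]:
                if (ca_str[pos], cb_str[pos]) in _TRANSITIONS:
                    ts[da] += 1
                else:
                    tv[da] += 1
    est, weights = [], []
    for cls in (0, 4):
        if L[cls] < 1:
            continue
        _, alpha_t, beta_t = _k80_distance(ts[cls] / L[cls], tv[cls] / L[cls])
        if math.isfinite(alpha_t) and beta_t > 0 and alpha_t > 0:
            est.append(alpha_t / beta_t)
            weights.append(L[cls])
    if not est:
        logger.warning(
            "%s/%s: kappa not estimable; falling back to 1", ca.gene_a, ca.gene_b
        )
        return 1.0
    return float(np.average(est, weights=weights))


def _weighted_sites(
    tables: _CodeTables, pi: np.ndarray, kappa: float
) -> np.ndarray:
    """Per-codon synonymous site counts with pi/kappa mutation weights.

    Each codon position contributes its weighted synonymous fraction
    (weights ``pi[target] * kappa^[transition]``, stop targets excluded),
    normalised per position exactly as NG86 normalises its unweighted
    fractions — so s + n = 3 per codon and the kappa = 1 / uniform case
    reduces to NG86's counts."""
    n = len(tables.sense_codons)
    w = pi[tables.nb_to] * np.where(tables.nb_ts, kappa, 1.0)
    group = tables.nb_from * 3 + tables.nb_pos  # (codon, position) cell
    syn = np.zeros(n * 3)
    tot = np.zeros(n * 3)
    np.add.at(syn, group, np.where(tables.nb_syn, w, 0.0))
    np.add.at(tot, group, w)
    with np.errstate(invalid="ignore"):
        frac = np.where(tot > 0, syn / tot, 0.0)
    return frac.reshape(n, 3).sum(axis=1)


def _weighted_differences(
    tables: _CodeTables,
    pair_counts: dict[tuple[int, int], int],
    pi: np.ndarray,
    kappa: float,
    omega: float,
) -> tuple[float, float, float, float]:
    """(Sd_ts, Sd_tv, Nd_ts, Nd_tv) with pathway weights pi * kappa * omega.

    Pathways are weighted by the product over steps of
    ``pi[target] * kappa^[transition] * omega^[nonsynonymous]`` and
    renormalised over stop-free pathways; the unordered orientation
    (smaller codon index first) is used so estimates are symmetric in the
    two sequences.
    """
    omega_w = max(omega, 1e-9)
    sd_ts = sd_tv = nd_ts = nd_tv = 0.0
    for (i, j), count in pair_counts.items():
        if i == j:
            continue
        lo, hi = (i, j) if i < j else (j, i)
        paths = tables.pathways(lo, hi)
        a, b = tables.sense_codons[lo], tables.sense_codons[hi]
        pos_ts = {
            p: (a[p], b[p]) in _TRANSITIONS for p in range(3) if a[p] != b[p]
        }
        if paths is None:
            for p, is_ts in pos_ts.items():
                if is_ts:
                    sd_ts += 0.5 * count
                    nd_ts += 0.5 * count
                else:
                    sd_tv += 0.5 * count
                    nd_tv += 0.5 * count
            continue
        weights = []
        for path in paths:
            w = 1.0
            for tgt, is_ts, is_syn, _pos in path:
                w *= pi[tgt] * (kappa if is_ts else 1.0)
                if not is_syn:
                    w *= omega_w
            weights.append(w)
        total = sum(weights)
        if total <= 0:
            weights = [1.0] * len(paths)
            total = float(len(paths))
        for w, path in zip(weights, paths):
            frac = w / total
            for tgt, is_ts, is_syn, _pos in path:
                if is_syn and is_ts:
                    sd_ts += frac * count
                elif is_syn:
                    sd_tv += frac * count
                elif is_ts:
                    nd_ts += frac * count
                else:
                    nd_tv += frac * count
    return sd_ts, sd_tv, nd_ts, nd_tv


def yn00_estimate(
    ca: CodonAlignment,
    fix_kappa: float | None = None,
    codon_freqs: str = "f3x4",
    tol: float = 1e-6,
    max_iter: int = 100,
) -> DnDsEstimate:
    """YN00-style dN/dS with kappa and codon-frequency weighting.

    ``codon_freqs`` is ``"f3x4"`` (estimated from the pair) or
    ``"uniform"``; ``fix_kappa`` bypasses the K80 kappa estimation (with
    ``fix_kappa=1`` and uniform frequencies the method reduces to NG86's
    site counting).  Omega is iterated to ``tol`` because the pathway
    weights depend on it; non-convergence is flagged, not raised.
    """
    if not ca.codon_columns:
        raise ValueError(f"{ca.gene_a}/{ca.gene_b}: empty codon alignment")
    tables = code_tables(ca.table_id)
    kappa = fix_kappa if fix_kappa is not None else estimate_kappa(ca)
    if codon_freqs == "uniform":
        pi = np.full(len(tables.sense_codons), 1.0 / len(tables.sense_codons))
    elif codon_freqs == "f3x4":
        pi = f3x4_frequencies(ca)
    else:
        raise ValueError(f"unknown codon_freqs {codon_freqs!r}")

    ia, ib = _column_indices(ca)
    s_codon = _weighted_sites(tables, pi, kappa)
    S = 0.5 * (s_codon[ia].sum() + s_codon[ib].sum())
    L = len(ca.codon_columns)
    N = 3.0 * L - S

    pair_counts: dict[tuple[int, int], int] = {}
    for i, j in zip(ia, ib):
        if i != j:
            key = (int(i), int(j))
            pair_counts[key] = pair_counts.get(key, 0) + 1

    omega = 1.0
    converged = False
    Sd = Nd = 0.0
    dS = dN = 0.0
    for _ in range(max_iter):
        sd_ts, sd_tv, nd_ts, nd_tv = _weighted_differences(
            tables, pair_counts, pi, kappa, omega
        )
        Sd, Nd = sd_ts + sd_tv, nd_ts + nd_tv
        dS = _k80_distance(sd_ts / S, sd_tv / S)[0] if S > 0 else 0.0
        dN = _k80_distance(nd_ts / N, nd_tv / N)[0] if N > 0 else 0.0
        if dS == 0.0 or not math.isfinite(dS) or not math.isfinite(dN):
            converged = True
            break
        new_omega = dN / dS
        if abs(new_omega - omega) < tol:
            omega = new_omega
            converged = True
            break
        omega = new_omega
    if not converged:
        logger.warning("%s/%s: YN00 omega did not converge", ca.gene_a, ca.gene_b)
    return _finish_estimate(
        ca.gene_a, ca.gene_b, "YN00", S, N, Sd, Nd, dS, dN, kappa, converged, L
    )


def estimate_dnds(ca: CodonAlignment, method: str = "YN00") -> DnDsEstimate:
    if method.upper() == "NG86":
        return ng86_estimate(ca)
    if method.upper() == "YN00":
        return yn00_estimate(ca)
    raise ValueError(f"unknown dN/dS method {method!r}")


# ---------------------------------------------------------------------------
# filters and summaries


def apply_saturation_filters(
    estimates: list[DnDsEstimate],
    ds_min: float = DS_MIN,
    ds_max: float = DS_MAX,
    omega_max: float = OMEGA_MAX,
) -> tuple[list[DnDsEstimate], list[tuple[DnDsEstimate, str]]]:
    """Discard unreliable/saturated estimates.

    An estimate is discarded iff ``dS < ds_min`` OR ``dS > ds_max`` OR
    ``omega > omega_max`` (all comparisons strict); the first matching rule
    in that order labels the discard.  Sentinel omegas (dS = 0 -> 999) and
    saturated infinities fall out of the same three rules.
    """
    retained, discarded = [], []
    for est in estimates:
        if est.dS < ds_min:
            discarded.append((est, f"dS < {ds_min:g}"))
        elif est.dS > ds_max:
            discarded.append((est, f"dS > {ds_max:g}"))
        elif est.omega > omega_max:
            discarded.append((est, f"dN/dS > {omega_max:g}"))
        else:
            retained.append(est)
    return retained, discarded


def summarize_genome_pair(
    retained: list[DnDsEstimate],
    n_orthologs: int,
    cds_count_a: int,
    cds_count_b: int,
    ani_pct: float | None = None,
    genome_a: str = "",
    genome_b: str = "",
    size_a_bp: int = 0,
    size_b_bp: int = 0,
    coding_density_a: float | None = None,
    coding_density_b: float | None = None,
    retention_fraction: float = RETENTION_FRACTION,
    discard_reasons: dict | None = None,
) -> GenomePairSummary:
    """Per-pair mean dN/dS with SEM and the coding-capacity retention rule.

    The pair is kept only when the retained orthologs amount to at least
    ``retention_fraction`` (default 5%, inclusive) of the two genomes'
    average CDS count; with fewer than two retained orthologs the SEM is
    undefined and the pair is dropped regardless.
    """
    if cds_count_a <= 0 or cds_count_b <= 0:
        raise ValueError("CDS counts must be positive")
    omegas = [e.omega for e in retained]
    n_ret = len(omegas)
    capacity = 0.5 * (cds_count_a + cds_count_b)
    fraction = n_ret / capacity
    mean_omega = float(np.mean(omegas)) if n_ret else None
    sem_omega = (
        float(np.std(omegas, ddof=1) / math.sqrt(n_ret)) if n_ret >= 2 else None
    )
    keep = n_ret >= 2 and fraction >= retention_fraction
    return GenomePairSummary(
        genome_a=genome_a,
        genome_b=genome_b,
        n_orthologs=n_orthologs,
        n_retained=n_ret,
        mean_omega=mean_omega,
        sem_omega=sem_omega,
        retained_fraction_of_capacity=fraction,
        keep=keep,
        ani_pct=ani_pct,
        size_a_cds=cds_count_a,
        size_b_cds=cds_count_b,
        size_a_bp=size_a_bp,
        size_b_bp=size_b_bp,
        coding_density_a=coding_density_a,
        coding_density_b=coding_density_b,
        discard_reasons=discard_reasons or {},
    )
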