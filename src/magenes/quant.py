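"""Gene abundance: coverage summarization, geTMM normalization, aggregation.

Per-gene abundance from read mapping is summarized as a trimmed mean of
per-base depths, zeroed when less than 75% of the gene is covered — the
same gate used when counting genes present in a metagenome.

Count matrices are normalized with geTMM: reads per kilobase (RPK) to
remove gene-length bias, then TMM (trimmed mean of M-values) scaling
factors computed on the RPK matrix to remove compositional bias, yielding
per-million values comparable across samples.  The TMM internals follow
the canonical recipe: reference sample chosen by 75th-percentile count
fraction, log-ratios doubly trimmed (30% on M, 5% on A), precision
weights from the delta-method variance of the log-ratio, and factors
rescaled to geometric mean one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .catalog import dereplicate
from .homology import DEFAULT_PARAMS, ScoringParams
from .seq_io import CountMatrix, SeqRecord


@dataclass
class DepthVector:
    gene_id: str
    depths: np.ndarray  # per-base, length == gene length (bp)

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths)
        if self.depths.ndim != 1 or self.depths.size == 0:
            raise ValueError("depths must be a nonempty 1-D vector")
        if (self.depths < 0).any():
            raise ValueError("depths must be nonnegative")


@dataclass
class NormalizedMatrix:
    values: pd.DataFrame  # genes x samples
    tmm_factors: pd.Series  # per sample, geometric mean 1
    normalization: str = "geTMM"


def summarize_coverage(
    d: DepthVector,
    trim_frac: float = 0.05,
    min_cov_frac: float = 0.75,
) -> float:
    """Trimmed-mean depth, gated on covered fraction.

    If fewer than ``min_cov_frac`` of positions have depth >= 1 the gene is
    called absent (0.0).  Otherwise the lowest and highest
    ``floor(trim_frac * L)`` positions are dropped and the rest averaged.
    """
    if not (0.0 <= trim_frac < 0.5):
        raise ValueError("trim_frac must be in [0, 0.5)")
    depths = d.depths
    L = depths.size
    covered = float((depths >= 1).sum()) / L
    if covered < min_cov_frac:
        return 0.0
    k = int(math.floor(trim_frac * L))
    trimmed = np.sort(depths)[k : L - k] if k > 0 else depths
    return float(trimmed.mean())


def _as_frame(counts: CountMatrix | pd.DataFrame) -> pd.DataFrame:
    if isinstance(counts, CountMatrix):
        return counts.counts.astype(float)
    return counts.astype(float)


def tmm_factors(
    counts: CountMatrix | pd.DataFrame,
    trim_M: float = 0.30,
    trim_A: float = 0.05,
) -> pd.Series:
    """TMM scaling factors, one per sample, geometric mean 1.

    The reference sample is the one whose 75th-percentile count fraction is
    closest to the across-sample mean.  For each sample, M (log2 ratio of
    count fractions vs the reference) and A (average log2 abundance) are
    computed on genes positive in both; the top and bottom ``trim_M`` of M
    and ``trim_A`` of A are discarded; the factor is 2 to the
    precision-weighted mean of the surviving M values.
    """
    df = _as_frame(counts)
    if df.shape[1] < 2:
        return pd.Series(1.0, index=df.columns, name="tmm_factor")
    lib = df.sum(axis=0)
    zero = lib[lib == 0]
    if len(zero):
        raise ValueError(f"sample {zero.index[0]!r} has all-zero counts")
    frac = df.div(lib, axis=1)
    q75 = frac.quantile(0.75, axis=0)
    ref = (q75 - q75.mean()).abs().idxmin()
    y_r = df[ref].values
    N_r = lib[ref]
    factors = {}
    for s in df.columns:
        if s == ref:
            factors[s] = 1.0
            continue
        y_s = df[s].values
        N_s = lib[s]
        both = (y_s > 0) & (y_r > 0)
        ys, yr = y_s[both], y_r[both]
        if ys.size == 0:
            raise ValueError(f"no genes positive in both {s!r} and reference {ref!r}")
        M = np.log2((ys / N_s) / (yr / N_r))
        A = 0.5 * np.log2((ys / N_s) * (yr / N_r))
        w = (N_s - ys) / (N_s * ys) + (N_r - yr) / (N_r * yr)
        n = M.size
        loM = math.floor(n * trim_M) + 1
        hiM = n + 1 - loM
        loA = math.floor(n * trim_A) + 1
        hiA = n + 1 - loA
        rM = pd.Series(M).rank(method="average").values
        rA = pd.Series(A).rank(method="average").values
        keep = (rM >= loM) & (rM <= hiM) & (rA >= loA) & (rA <= hiA)
        if keep.sum() == 0 or np.sum(w[keep]) == 0:
            factors[s] = 1.0
        else:
            f = np.sum(M[keep] / w[keep]) / np.sum(1.0 / w[keep])
            factors[s] = 2.0 ** f
    fac = pd.Series(factors, name="tmm_factor").reindex(df.columns)
    fac /= np.exp(np.log(fac).mean())  # geometric mean 1
    return fac


def getmm(counts: CountMatrix, trim_M: float = 0.30, trim_A: float = 0.05) -> NormalizedMatrix:
    """Gene-length-corrected TMM normalization.

    RPK = count / (length_bp / 1000); TMM factors are computed on the RPK
    matrix; normalized value = RPK / (factor_s * sum(RPK_s)) * 1e6 — i.e.
    counts per million of the effective (factor-scaled) RPK library.
    """
    lengths = counts.gene_lengths.loc[counts.gene_ids]
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    rpk = counts.counts.astype(float).div(lengths.values / 1000.0, axis=0)
    if counts.counts.shape[1] == 1:
        fac = pd.Series(1.0, index=counts.counts.columns, name="tmm_factor")
    else:
        fac = tmm_factors(rpk, trim_M=trim_M, trim_A=trim_A)
    eff = fac * rpk.sum(axis=0)
    values = rpk.div(eff, axis=1) * 1e6
    return NormalizedMatrix(values=values, tmm_factors=fac)


def aggregate(
    norm: NormalizedMatrix | pd.DataFrame,
    key: dict[str, str],
) -> pd.DataFrame:
    """Sum normalized gene abundances into groups (gene type or role).

    Returns samples x groups.  Genes missing from ``key`` are dropped; the
    number dropped is recorded in ``result.attrs['n_ungrouped']``.
    """
    values = norm.values if isinstance(norm, NormalizedMatrix) else norm
    grouped = values.loc[values.index.isin(key)]
    n_ungrouped = values.shape[0] - grouped.shape[0]
    groups = pd.Series({g: key[g] for g in grouped.index})
    out = grouped.groupby(groups).sum().T
    out.attrs["n_ungrouped"] = n_ungrouped
    return out


def accumulation_curve(
    per_subject_gene_seqs: Sequence[Sequence[SeqRecord]],
    threshold: float = 0.99,
    params: ScoringParams = DEFAULT_PARAMS,
    n_permutations: int = 0,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Gene discovery curve: nonredundant gene count after each added subject.

    Step k is the cluster count of :func:`catalog.dereplicate` on the union
    of the first k subjects' sequences (computed incrementally; equals the
    batch recomputation).  With ``n_permutations`` > 0 the subject order is
    shuffled that many times and the mean and sd per step are returned
    alongside the given-order curve.
    """
    def one_order(order: Sequence[int]) -> list[int]:
        pool: list[SeqRecord] = []
        out = []
        for idx in order:
            pool.extend(per_subject_gene_seqs[idx])
            out.append(dereplicate(pool, threshold=threshold, params=params).n_clusters)
        return out

    n = len(per_subject_gene_seqs)
    given = one_order(range(n))
    df = pd.DataFrame({"step": np.arange(1, n + 1), "genes": given})
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        curves = np.array(
            [one_order(rng.permutation(n)) for _ in range(n_permutations)], dtype=float
        )
        df["perm_mean"] = curves.mean(axis=0)
        df["perm_sd"] = curves.std(axis=0, ddof=1) if n_permutations > 1 else 0.0
    return df


def read_depths_tsv(path) -> list[DepthVector]:
    """Read per-base depths from TSV columns (gene_id, position, depth)."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for gid, grp in df.groupby("gene_id", sort=False):
        grp = grp.sort_values("position")
        L = int(grp["position"].max()) + 1
        depths = np.zeros(L, dtype=int)
        depths[grp["position"].values] = grp["depth"].values
        out.append(DepthVector(gene_id=str(gid), depths=depths))
    return out
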