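"""Local and stage-level single-cell landscape entropy (SCLE) scores.

For a gene g with first-order neighbors g_1..g_Q in the template network
and the cells of one stage t, the local score is

    H_t(g) = [ -1/ln(Q) * sum_i p_i ln p_i ] * SD(g at t)

where the weights p_i are the absolute Pearson correlations |PCC(g, g_i)|
normalized to a simplex.  The bracketed factor is a normalized Shannon
entropy in [0, 1]: it is maximal when the gene's neighborhood coordination
is spread evenly and small when dominated by a single partner.  The
per-stage score H_t sums the R largest local scores (R = top 5% of network
genes by default); a sharp rise of H_t flags the critical, pre-transition
stage, and its top-R contributors are the candidate DNB module.

Degenerate cases follow explicit conventions: a constant center gene has
SD = 0 and hence score 0; all-zero weights give entropy 0; a single
neighbor (Q = 1) gives entropy 1 (the uniform one-outcome limit,
configurable); 0*ln(0) = 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from scle.expression_io import StageSeries
from scle.network import LocalNetwork, TemplateNetwork


@dataclass(frozen=True)
class LocalScore:
    """The local SCLE score of one gene at one stage."""

    gene: str
    stage: str
    sd: float
    weights: tuple[float, ...]
    entropy: float
    score: float


@dataclass
class ScleProfile:
    """Per-gene and per-stage SCLE scores with the critical-stage call."""

    genes: tuple[str, ...]
    stage_order: tuple[str, ...]
    local_scores: pd.DataFrame  # columns: gene, stage, sd, entropy, score
    stage_scores: pd.Series  # H_t indexed by stage label
    R: int
    top_fraction: float
    top_genes: dict[str, tuple[str, ...]]
    critical_stage: str | None = None
    fold_change: float | None = None
    end_of_series_warning: bool = False
    pvalue: float | None = None


@dataclass(frozen=True)
class CriticalCall:
    stage: str
    fold_change: float
    end_of_series_warning: bool


def pearson_abs(x, y) -> float:
    """Absolute Pearson correlation |PCC(x, y)|; 0 if either vector is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.ndim != 1 or len(x) < 3:
        raise ValueError("pearson_abs requires 1-d vectors of length >= 3")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt(float(xc @ xc)) * math.sqrt(float(yc @ yc))
    if denom == 0.0:
        return 0.0
    return min(abs(float(xc @ yc) / denom), 1.0)


def _entropy_from_weights(weights: np.ndarray, q1_entropy: float) -> float:
    """Normalized Shannon entropy of simplex-normalized raw weights."""
    s = float(weights.sum())
    q = len(weights)
    if s <= 0.0:
        return 0.0
    if q == 1:
        return q1_entropy
    p = weights[weights > 0] / s
    ent = -float(p @ np.log(p)) / math.log(q)
    return min(max(ent, 0.0), 1.0)


def local_scle(
    series: StageSeries,
    ln: LocalNetwork,
    stage: str,
    q1_entropy: float = 1.0,
) -> LocalScore:
    """Local SCLE score of ``ln.center`` at ``stage`` (reference scalar path)."""
    if stage not in series.stage_order:
        raise ValueError(f"unknown stage {stage!r}")
    gi = series.matrix.gene_index()
    cols = series.stage_columns(stage)
    center = series.matrix.values[gi[ln.center], cols]
    sd = float(np.std(center, ddof=1))
    raw = np.array(
        [
            pearson_abs(center, series.matrix.values[gi[nb], cols])
            for nb in ln.neighbors
        ]
    )
    entropy = _entropy_from_weights(raw, q1_entropy)
    s = raw.sum()
    weights = tuple((raw / s).tolist()) if s > 0 else tuple(raw.tolist())
    return LocalScore(
        gene=ln.center,
        stage=stage,
        sd=sd,
        weights=weights,
        entropy=entropy,
        score=entropy * sd,
    )


# ---------------------------------------------------------------------------
# vectorized stage scoring


def _abs_corr(X: np.ndarray) -> np.ndarray:
    """|Pearson| matrix over rows of X; constant rows correlate 0 with everything."""
    Xc = X - X.mean(axis=1, keepdims=True)
    norm = np.sqrt((Xc * Xc).sum(axis=1))
    safe = np.where(norm > 0, norm, 1.0)
    Y = Xc / safe[:, None]
    Y[norm == 0] = 0.0
    C = np.abs(Y @ Y.T)
    np.clip(C, 0.0, 1.0, out=C)
    return C


class _NetworkScorer:
    """Precomputed adjacency structure for fast per-stage scoring."""

    def __init__(self, series: StageSeries, network: TemplateNetwork, q1_entropy: float):
        self.q1_entropy = q1_entropy
        self.net_genes = network.nodes  # sorted
        gi = series.matrix.gene_index()
        missing = [g for g in self.net_genes if g not in gi]
        if missing:
            raise ValueError(
                f"network gene {missing[0]!r} is not in the expression matrix"
            )
        self.values = series.matrix.values[[gi[g] for g in self.net_genes], :]
        pos = {g: i for i, g in enumerate(self.net_genes)}
        indptr = [0]
        indices: list[int] = []
        for g in self.net_genes:
            nbrs = sorted(network.graph.neighbors(g))
            indices.extend(pos[n] for n in nbrs)
            indptr.append(len(indices))
        self.indptr = np.asarray(indptr, dtype=np.int64)
        self.indices = np.asarray(indices, dtype=np.int64)
        self.rows = np.repeat(
            np.arange(len(self.net_genes), dtype=np.int64), np.diff(self.indptr)
        )
        self.Q = np.diff(self.indptr)

    def score_columns(self, cols: np.ndarray):
        """Return (sd, entropy, score) arrays over network genes for one cell set."""
        X = self.values[:, cols]
        C = _abs_corr(X)
        sd = X.std(axis=1, ddof=1)
        w = C[self.rows, self.indices]
        starts = self.indptr[:-1]
        s = np.add.reduceat(w, starts)
        # simplex-normalize within each ego network, then -sum p ln p
        p = w / np.repeat(np.where(s > 0, s, 1.0), self.Q)
        plogp = np.where(p > 0, p * np.log(np.where(p > 0, p, 1.0)), 0.0)
        t = np.add.reduceat(plogp, starts)
        ent = np.zeros(len(self.net_genes))
        multi = (self.Q > 1) & (s > 0)
        ent[multi] = -t[multi] / np.log(self.Q[multi])
        ent[(self.Q == 1) & (s > 0)] = self.q1_entropy
        np.clip(ent, 0.0, 1.0, out=ent)
        return sd, ent, ent * sd


def _num_top(top_fraction: float, m: int) -> int:
    if not (0.0 < top_fraction <= 1.0):
        raise ValueError("top_fraction must be in (0, 1]")
    return max(1, math.ceil(top_fraction * m))


def _top_order(scores: np.ndarray, genes: np.ndarray) -> np.ndarray:
    """Indices sorted by score descending, ties broken lexicographically."""
    return np.lexsort((genes, -scores))


def stage_scle(
    series: StageSeries,
    network: TemplateNetwork,
    top_fraction: float = 0.05,
    q1_entropy: float = 1.0,
) -> ScleProfile:
    """Compute local scores for every network gene at every stage and H_t.

    ``R = ceil(top_fraction * M)`` with M the template-network node count;
    H_t is the sum of the R largest local scores at stage t, with ranking
    ties broken lexicographically by gene symbol for reproducibility.
    """
    scorer = _NetworkScorer(series, network, q1_entropy)
    genes = np.asarray(scorer.net_genes)
    R = _num_top(top_fraction, len(genes))
    rows = []
    stage_scores = {}
    top_genes = {}
    for stage in series.stage_order:
        sd, ent, score = scorer.score_columns(series.stage_columns(stage))
        order = _top_order(score, genes)
        top = order[:R]
        stage_scores[stage] = float(score[top].sum())
        top_genes[stage] = tuple(genes[top])
        rows.append(
            pd.DataFrame(
                {"gene": genes, "stage": stage, "sd": sd, "entropy": ent, "score": score}
            )
        )
    return ScleProfile(
        genes=tuple(genes),
        stage_order=series.stage_order,
        local_scores=pd.concat(rows, ignore_index=True),
        stage_scores=pd.Series(stage_scores, name="H_t").reindex(list(series.stage_order)),
        R=R,
        top_fraction=top_fraction,
        top_genes=top_genes,
    )


def detect_critical_stage(profile: ScleProfile) -> CriticalCall:
    """Call the critical stage at the H_t argmax (ties -> earliest stage).

    Also reports the fold change over the preceding stage (``inf`` when the
    peak is the first stage or the preceding score is zero) and a warning
    flag when the peak falls on the final stage, where a genuine peak is
    indistinguishable from a monotone rise.
    """
    h = profile.stage_scores.to_numpy(dtype=float)
    idx = int(np.argmax(h))  # np.argmax returns the first maximum
    stage = profile.stage_order[idx]
    if idx == 0 or h[idx - 1] == 0.0:
        fold = math.inf
    else:
        fold = float(h[idx] / h[idx - 1])
    warn = idx == len(h) - 1
    profile.critical_stage = stage
    profile.fold_change = fold
    profile.end_of_series_warning = warn
    return CriticalCall(stage=stage, fold_change=fold, end_of_series_warning=warn)


def permutation_pvalue(
    series: StageSeries,
    network: TemplateNetwork,
    profile: ScleProfile,
    B: int,
    seed: int,
    q1_entropy: float = 1.0,
) -> float:
    """Stage-label permutation p-value for the peak stage score.

    Cell -> stage assignments are shuffled B times preserving stage sizes;
    each permutation recomputes max_t H_t, and
    p = (1 + #{perm max >= observed max}) / (B + 1).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    scorer = _NetworkScorer(series, network, q1_entropy)
    genes = np.asarray(scorer.net_genes)
    R = profile.R
    observed = float(profile.stage_scores.max())
    all_cols = np.concatenate([series.stage_columns(s) for s in series.stage_order])
    sizes = [len(series.stage_columns(s)) for s in series.stage_order]
    bounds = np.cumsum(sizes)[:-1]
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(B):
        perm = all_cols[rng.permutation(len(all_cols))]
        perm_max = -math.inf
        for group in np.split(perm, bounds):
            _, _, score = scorer.score_columns(group)
            top = _top_order(score, genes)[:R]
            perm_max = max(perm_max, float(score[top].sum()))
        if perm_max >= observed:
            count += 1
    p = (1 + count) / (B + 1)
    profile.pvalue = p
    return p
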