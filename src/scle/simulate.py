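"""Planted-transition simulator for staged single-cell expression data.

Cells are drawn stage by stage from a multivariate normal in log space
whose covariance carries the correlation structure of a generated template
network: at baseline every gene has SD sigma0 and network-adjacent pairs
correlate at rho_base; at the planted critical stage t* a connected module
of genes has its SD inflated to sigma_ratio * sigma0, all within-module
pairs correlate at rho_in, and module-to-outside edge correlations are
damped by rho_out_factor.  This realizes the three DNB signatures (SD_in
up, PCC_in up, PCC_out down) generatively, so recovery of t* and the
module can be tested against known truth.

Log-space draws are truncated at zero and mapped to count-like values via
exp(x) - 1, so the ln(1+x) normalization recovers the latent scale.  The
baseline log-space mean (mu0 = 5) keeps truncation negligible even for the
inflated module SD.  An optional deterministic rise-then-fall mean profile
on one non-module neighbor gene plants a reversal target.

The generator emulates the covariance structure the SCLE statistic reads;
it deliberately omits scRNA-seq dropout, library-size variation and batch
structure (see the methods note).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from scle.expression_io import ExpressionMatrix
from scle.network import TemplateNetwork

_EIG_FLOOR = 1e-8


@dataclass(frozen=True)
class SimulationConfig:
    """Generation parameters; the defaults define the benchmark conditions."""

    M: int = 200  # genes
    T: int = 6  # stages
    n_per_stage: int = 60  # cells per stage
    module_size: int = 20  # planted DNB module size m
    critical_stage: int = 4  # 1-based planted t*
    sigma0: float = 0.5  # baseline log-space SD
    sigma_ratio: float = 3.0  # module SD inflation at t*
    rho_base: float = 0.1  # baseline correlation on network edges
    rho_in: float = 0.8  # within-module correlation at t*
    rho_out_factor: float = 0.25  # module-to-outside edge damping at t*
    mu0: float = 5.0  # baseline log-space mean
    network_model: str = "erdos_renyi"  # or "barabasi_albert"
    network_param: float = 0.1  # p for ER, attachment k for BA
    neighbor_reversal: bool = False
    reversal_amplitude: float = 1.0
    poisson_counts: bool = False  # optional count layer: Poisson(exp(x)-1)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.module_size < self.M):
            raise ValueError("module_size must satisfy 0 < m < M")
        if not (1 <= self.critical_stage <= self.T):
            raise ValueError("critical_stage must lie in 1..T")
        if not (0.0 <= self.rho_base <= self.rho_in < 1.0):
            raise ValueError("need 0 <= rho_base <= rho_in < 1")
        if self.sigma_ratio < 1.0:
            raise ValueError("sigma_ratio must be >= 1")
        if self.n_per_stage < 7:
            raise ValueError("n_per_stage must be >= 7")


@dataclass(frozen=True)
class SyntheticTruth:
    planted_module: frozenset[str]
    critical_stage: str
    reversal_gene: str | None
    config: SimulationConfig


def _gene_name(i: int, width: int) -> str:
    return f"G{i:0{width}d}"


def _generate_network(config: SimulationConfig, rng: np.random.Generator) -> nx.Graph:
    net_seed = int(rng.integers(0, 2**31 - 1))
    if config.network_model == "erdos_renyi":
        g = nx.gnp_random_graph(config.M, float(config.network_param), seed=net_seed)
    elif config.network_model == "barabasi_albert":
        g = nx.barabasi_albert_graph(config.M, int(config.network_param), seed=net_seed)
    else:
        raise ValueError(f"unknown network_model {config.network_model!r}")
    # reattach isolated nodes so every gene has a local network
    nodes = np.arange(config.M)
    for v in sorted(nx.isolates(g)):
        others = nodes[nodes != v]
        g.add_edge(v, int(rng.choice(others)))
    return g


def _plant_module(
    g: nx.Graph, m: int, rng: np.random.Generator
) -> list[int]:
    """A connected m-node subgraph grown breadth-first from a seeded start."""
    comps = sorted((sorted(c) for c in nx.connected_components(g)), key=len, reverse=True)
    comp = comps[0]
    if len(comp) < m:
        raise ValueError(
            f"largest connected component has {len(comp)} < module_size={m} nodes"
        )
    start = int(rng.choice(comp))
    module = [start]
    seen = {start}
    frontier = [start]
    while len(module) < m:
        if not frontier:  # cannot happen inside a component of size >= m
            raise ValueError("breadth-first module growth exhausted the component")
        nxt: list[int] = []
        for v in frontier:
            for u in sorted(g.neighbors(v)):
                if u not in seen:
                    seen.add(u)
                    module.append(u)
                    nxt.append(u)
                    if len(module) == m:
                        return sorted(module)
        frontier = nxt
    return sorted(module)


def _nearest_pd_correlation(R: np.ndarray) -> np.ndarray:
    """Eigenvalue-clipped positive-definite repair, rescaled to unit diagonal."""
    vals, vecs = np.linalg.eigh(R)
    if vals.min() >= _EIG_FLOOR:
        return R
    vals = np.clip(vals, _EIG_FLOOR, None)
    fixed = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return fixed


def _stage_covariance(
    config: SimulationConfig,
    g: nx.Graph,
    module: list[int],
    at_critical: bool,
    stage_label: str,
):
    M = config.M
    R = np.eye(M)
    for a, b in g.edges:
        R[a, b] = R[b, a] = config.rho_base
    sd = np.full(M, config.sigma0)
    if at_critical:
        mod = np.asarray(module)
        in_mod = np.zeros(M, dtype=bool)
        in_mod[mod] = True
        # all within-module pairs cohere; module-boundary edges are damped
        for a, b in g.edges:
            if in_mod[a] != in_mod[b]:
                R[a, b] = R[b, a] = config.rho_base * config.rho_out_factor
        R[np.ix_(mod, mod)] = config.rho_in
        np.fill_diagonal(R, 1.0)
        sd[mod] = config.sigma_ratio * config.sigma0
    R = _nearest_pd_correlation(R)
    cov = R * np.outer(sd, sd)
    try:
        L = np.linalg.cholesky(cov + np.eye(M) * 1e-12)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            f"covariance repair failed at stage {stage_label}: {exc}"
        ) from exc
    return L


def _reversal_profile(config: SimulationConfig) -> np.ndarray:
    """Mean offset per stage: linear rise to the critical stage, then fall."""
    t = np.arange(1, config.T + 1, dtype=float)
    ts = float(config.critical_stage)
    up = (t - 1) / max(ts - 1, 1.0)
    down = (config.T - t) / max(config.T - ts, 1.0)
    return config.reversal_amplitude * np.where(t <= ts, up, down)


def simulate(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, dict[str, str], TemplateNetwork, SyntheticTruth]:
    """Generate (raw matrix, cell -> stage labels, template network, truth)."""
    rng = np.random.default_rng(config.seed)
    g = _generate_network(config, rng)
    module = _plant_module(g, config.module_size, rng)

    width = len(str(config.M - 1))
    genes = tuple(_gene_name(i, width) for i in range(config.M))
    gene_of = dict(enumerate(genes))

    reversal_gene_idx: int | None = None
    profile = np.zeros(config.T)
    if config.neighbor_reversal:
        boundary = sorted(
            {u for v in module for u in g.neighbors(v)} - set(module)
        )
        if not boundary:
            raise ValueError("module has no outside neighbors for reversal planting")
        reversal_gene_idx = int(rng.choice(boundary))
        profile = _reversal_profile(config)

    L_base = _stage_covariance(config, g, module, at_critical=False, stage_label="base")
    stage_labels = tuple(f"S{t}" for t in range(1, config.T + 1))
    blocks = []
    cells: list[str] = []
    stage_of_cell: dict[str, str] = {}
    for t, label in enumerate(stage_labels, start=1):
        at_crit = t == config.critical_stage
        L = (
            _stage_covariance(config, g, module, at_critical=True, stage_label=label)
            if at_crit
            else L_base
        )
        mu = np.full(config.M, config.mu0)
        if reversal_gene_idx is not None:
            mu[reversal_gene_idx] += profile[t - 1]
        z = mu[:, None] + L @ rng.standard_normal((config.M, config.n_per_stage))
        np.clip(z, 0.0, None, out=z)
        counts = np.expm1(z)
        if config.poisson_counts:
            counts = rng.poisson(counts).astype(float)
        blocks.append(counts)
        for i in range(config.n_per_stage):
            cell = f"cell_{label}_{i:03d}"
            cells.append(cell)
            stage_of_cell[cell] = label

    values = np.concatenate(blocks, axis=1)
    matrix = ExpressionMatrix(genes=genes, cells=tuple(cells), values=values)
    relabeled = nx.relabel_nodes(g, gene_of)
    network = TemplateNetwork(
        graph=relabeled,
        provenance={
            "source": "synthetic",
            "network_model": config.network_model,
            "network_param": config.network_param,
            "seed": config.seed,
        },
    )
    truth = SyntheticTruth(
        planted_module=frozenset(gene_of[i] for i in module),
        critical_stage=stage_labels[config.critical_stage - 1],
        reversal_gene=(
            gene_of[reversal_gene_idx] if reversal_gene_idx is not None else None
        ),
        config=config,
    )
    return matrix, stage_of_cell, network, truth


def null_config(seed: int = 0, **overrides) -> SimulationConfig:
    """A no-signal configuration: identical covariance at every stage."""
    params = dict(sigma_ratio=1.0, rho_out_factor=1.0, seed=seed)
    params["rho_in"] = overrides.pop("rho_base", SimulationConfig.rho_base)
    params["rho_base"] = params["rho_in"]
    params.update(overrides)
    return SimulationConfig(**params)


def write_truth_json(truth: SyntheticTruth, path: str | Path) -> None:
    payload = {
        "planted_module": sorted(truth.planted_module),
        "critical_stage": truth.critical_stage,
        "reversal_gene": truth.reversal_gene,
        "config": asdict(truth.config),
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
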