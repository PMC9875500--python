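"""DNB gene-module extraction and the three-property statistics.

A dynamic-network-biomarker module announces an approaching critical
transition through three signatures at the critical stage: the module
genes' standard deviation (SD_in) rises sharply, their mutual correlation
(PCC_in) rises sharply, and their correlation with genes outside the
module (PCC_out) falls.  Here the module is the set of top-R local-score
contributors at the called critical stage, and the statistics are tracked
across every stage so the signature can be inspected.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from scle.core import ScleProfile
from scle.expression_io import StageSeries
from scle.network import TemplateNetwork

logger = logging.getLogger(__name__)

DEFAULT_MAX_PAIRS = 100_000


@dataclass
class DnbReport:
    dnb_genes: frozenset[str]
    neighbors: frozenset[str]
    statistics: pd.DataFrame  # columns: stage, SD_in, PCC_in, PCC_out


def identify_dnb_genes(profile: ScleProfile) -> frozenset[str]:
    """The top-R genes by local score at the critical stage (the H_t* summands)."""
    if profile.critical_stage is None:
        raise ValueError("critical stage has not been called; run detect_critical_stage")
    return frozenset(profile.top_genes[profile.critical_stage])


def _unit_rows(X: np.ndarray) -> np.ndarray:
    Xc = X - X.mean(axis=1, keepdims=True)
    norm = np.sqrt((Xc * Xc).sum(axis=1))
    Y = Xc / np.where(norm > 0, norm, 1.0)[:, None]
    Y[norm == 0] = 0.0
    return Y


def dnb_statistics(
    series: StageSeries,
    dnb_genes,
    non_dnb_genes,
    stage: str,
    max_pairs: int = DEFAULT_MAX_PAIRS,
    seed: int = 0,
) -> tuple[float, float, float]:
    """(SD_in, PCC_in, PCC_out) of the DNB group at one stage.

    SD_in is the mean per-gene sample SD; PCC_in the mean |PCC| over all
    unordered DNB pairs; PCC_out the mean |PCC| over DNB x non-DNB pairs,
    uniformly subsampled without replacement (seeded) when the pair count
    exceeds ``max_pairs``.  A singleton DNB group has no internal pairs:
    PCC_in is reported as NaN with a warning.
    """
    dnb = sorted(set(dnb_genes))
    other = sorted(set(non_dnb_genes) - set(dnb))
    if not dnb:
        raise ValueError("dnb_genes is empty")
    gi = series.matrix.gene_index()
    cols = series.stage_columns(stage)
    Xd = series.matrix.values[[gi[g] for g in dnb], :][:, cols]
    sd_in = float(Xd.std(axis=1, ddof=1).mean())

    Yd = _unit_rows(Xd)
    if len(dnb) == 1:
        logger.warning("single-gene DNB group at stage %s: PCC_in undefined", stage)
        pcc_in = math.nan
    else:
        C = np.abs(Yd @ Yd.T)
        iu = np.triu_indices(len(dnb), k=1)
        pcc_in = float(np.clip(C[iu], 0.0, 1.0).mean())

    if not other:
        pcc_out = math.nan
    else:
        Xo = series.matrix.values[[gi[g] for g in other], :][:, cols]
        Yo = _unit_rows(Xo)
        total = len(dnb) * len(other)
        if total <= max_pairs:
            pcc_out = float(np.clip(np.abs(Yd @ Yo.T), 0.0, 1.0).mean())
        else:
            rng = np.random.default_rng(seed)
            flat = rng.choice(total, size=max_pairs, replace=False)
            ii, jj = np.divmod(flat, len(other))
            vals = np.abs((Yd[ii] * Yo[jj]).sum(axis=1))
            pcc_out = float(np.clip(vals, 0.0, 1.0).mean())
    return sd_in, pcc_in, pcc_out


def dnb_statistics_table(
    series: StageSeries,
    dnb_genes,
    non_dnb_genes,
    max_pairs: int = DEFAULT_MAX_PAIRS,
    seed: int = 0,
) -> pd.DataFrame:
    rows = []
    for stage in series.stage_order:
        sd_in, pcc_in, pcc_out = dnb_statistics(
            series, dnb_genes, non_dnb_genes, stage, max_pairs=max_pairs, seed=seed
        )
        rows.append(
            {"stage": stage, "SD_in": sd_in, "PCC_in": pcc_in, "PCC_out": pcc_out}
        )
    return pd.DataFrame(rows)


def find_dnb_neighbors(network: TemplateNetwork, dnb_genes) -> frozenset[str]:
    """First-order network neighbors of the DNB genes, excluding the DNB genes."""
    dnb = set(dnb_genes)
    out: set[str] = set()
    for g in sorted(dnb):
        if g not in network.graph:
            raise KeyError(f"DNB gene {g!r} is not in the template network")
        out.update(network.graph.neighbors(g))
    return frozenset(out - dnb)


def dnb_report(
    series: StageSeries,
    network: TemplateNetwork,
    profile: ScleProfile,
    max_pairs: int = DEFAULT_MAX_PAIRS,
    seed: int = 0,
) -> DnbReport:
    """Full DNB report: module, neighbor set, and per-stage three-property table."""
    dnb = identify_dnb_genes(profile)
    non_dnb = set(profile.genes) - dnb
    return DnbReport(
        dnb_genes=dnb,
        neighbors=find_dnb_neighbors(network, dnb),
        statistics=dnb_statistics_table(
            series, dnb, non_dnb, max_pairs=max_pairs, seed=seed
        ),
    )
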