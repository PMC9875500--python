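"""Independent brute-force reference for the SCLE statistics.

Deliberately naive: explicit Python loops, scipy.stats.pearsonr for the
correlations and statistics.stdev for the SD, with no code shared with the
vectorized implementation it cross-checks.
"""

import math
import statistics

from scipy.stats import pearsonr


def naive_abs_pcc(x, y):
    if statistics.pstdev(x) == 0 or statistics.pstdev(y) == 0:
        return 0.0
    return abs(pearsonr(list(x), list(y))[0])


def naive_entropy(raw_weights, q1_entropy=1.0):
    s = sum(raw_weights)
    q = len(raw_weights)
    if s == 0:
        return 0.0
    if q == 1:
        return q1_entropy
    acc = 0.0
    for w in raw_weights:
        p = w / s
        if p > 0:
            acc -= p * math.log(p)
    return acc / math.log(q)


def naive_local_score(center_values, neighbor_values, q1_entropy=1.0):
    sd = statistics.stdev(center_values)
    raw = [naive_abs_pcc(center_values, nb) for nb in neighbor_values]
    return naive_entropy(raw, q1_entropy) * sd


def naive_stage_scle(series, network, top_fraction=0.05, q1_entropy=1.0):
    """Per-stage {gene: local score} dicts, H_t dict, and top-R gene lists."""
    genes = sorted(network.graph.nodes)
    gi = {g: i for i, g in enumerate(series.matrix.genes)}
    r = max(1, math.ceil(top_fraction * len(genes)))
    local, stage_scores, top_genes = {}, {}, {}
    for stage in series.stage_order:
        cols = list(series.stage_columns(stage))
        scores = {}
        for g in genes:
            center = [series.matrix.values[gi[g], j] for j in cols]
            nbrs = sorted(network.graph.neighbors(g))
            neighbor_values = [
                [series.matrix.values[gi[n], j] for j in cols] for n in nbrs
            ]
            scores[g] = naive_local_score(center, neighbor_values, q1_entropy)
        ranked = sorted(scores, key=lambda g: (-scores[g], g))
        local[stage] = scores
        top_genes[stage] = ranked[:r]
        stage_scores[stage] = sum(scores[g] for g in ranked[:r])
    return local, stage_scores, top_genes
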