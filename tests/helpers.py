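"""Independent oracles used by the sampler tests.

The brute-force posterior enumerates every legal pedigree
configuration and weights it by likelihood x categorical prior —
no MCMC involved.
"""

from __future__ import annotations

import itertools
import math

import networkx as nx

from wolfped.pedigree_core import UNSAMPLED
from wolfped.pedigree_mcmc import TrioCalculator, build_candidates


def brute_force_posterior(
    genotypes,
    sexes,
    freqs,
    rates,
    n_unsampled_f=1.0,
    n_unsampled_m=1.0,
    candidates=None,
):
    """Exact per-offspring parent-pair marginals by full enumeration."""
    ids = sorted(genotypes)
    if candidates is None:
        candidates = build_candidates(genotypes, sexes)
    calc = TrioCalculator(genotypes, freqs, rates)
    ll = {o: calc.pair_loglik_matrix(o, *candidates[o]) for o in ids}

    def pairs_of(o):
        d, s = candidates[o]
        return [(dd, ss) for dd in list(d) + [UNSAMPLED] for ss in list(s) + [UNSAMPLED]]

    def legal(cfg):
        g = nx.DiGraph()
        g.add_nodes_from(cfg)
        for o, (d, s) in cfg.items():
            for p in (d, s):
                if p != UNSAMPLED:
                    g.add_edge(p, o)
        return nx.is_directed_acyclic_graph(g)

    marg = {o: {} for o in ids}
    total = 0.0
    for combo in itertools.product(*[pairs_of(o) for o in ids]):
        cfg = dict(zip(ids, combo))
        if not legal(cfg):
            continue
        logw = 0.0
        for o, (d, s) in cfg.items():
            dl, sl = candidates[o]
            di = dl.index(d) if d in dl else len(dl)
            si = sl.index(s) if s in sl else len(sl)
            logw += ll[o][di, si]
            logw += math.log(n_unsampled_f) if d == UNSAMPLED else 0.0
            logw += math.log(n_unsampled_m) if s == UNSAMPLED else 0.0
        w = math.exp(logw)
        total += w
        for o, pair in cfg.items():
            marg[o][pair] = marg[o].get(pair, 0.0) + w
    return {o: {k: v / total for k, v in m.items()} for o, m in marg.items()}
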