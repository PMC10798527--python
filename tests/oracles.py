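"""Independent oracles used by several test modules.

These deliberately re-derive quantities by the most direct route
available (per-group hand evaluation, fixed-point iteration) so the
solver implementations are checked against something they do not share
code with.
"""

from trophos.foodweb import production_rate


def eq2_ee(model, bm, gid):
    """Direct per-group evaluation of the mass-balance budget for EE."""
    g = bm.model.group(gid)
    losses = 0.0
    for j in bm.model.consumer_ids:
        cj = bm.model.group(j)
        losses += cj.biomass * cj.cb * bm.model.diet.fraction(gid, j)
    losses += g.emigration + bm.model.catch.total_removal(gid)
    losses -= g.immigration + g.ba
    return losses / production_rate(g)


def tl_fixed_point(diet, producer_ids, detritus_ids, consumer_ids, iters=300):
    """Fixed-point iteration TL <- 1 + D^T TL."""
    tl = {i: 1.0 for i in list(producer_ids) + list(detritus_ids) + list(consumer_ids)}
    for _ in range(iters):
        new = dict(tl)
        for j in consumer_ids:
            new[j] = 1.0 + sum(
                d * tl[int(i)] for i, d in diet.column(j).items() if d > 0
            )
        tl = new
    return tl
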