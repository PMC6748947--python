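"""Shared experiment used by both the property suite and the acceptance suite."""

import numpy as np

from loopfit.io_contacts import BinAnnotation
from loopfit.significance import CallConfig, call_loops
from loopfit.simulate import (
    decay_matrix,
    ipf_scale,
    matrix_to_contact_map,
    rescale_total,
    shuffle_coverage,
)


def shuffled_coverage_experiment(seed: int = 0, n: int = 200, binsize: int = 5000,
                                 n_shuffles: int = 5):
    """Simulate a pulldown of a loop-bearing source matrix by a coverage
    vector concentrated on peak bins, then by shuffled versions of it.

    Returns (n_loops_real, [n_loops_shuffled, ...]).
    """
    rng = np.random.default_rng(seed)
    M0 = decay_matrix(n, binsize, alpha=1.0, scale=4e6, rng=rng)
    peak = np.sort(rng.choice(n, size=40, replace=False))
    flags = np.zeros(n, dtype=bool)
    flags[peak] = True
    for _ in range(15):
        a, b = sorted(rng.choice(peak, 2, replace=False))
        if 40_000 <= (b - a) * binsize <= 800_000:
            M0[a, b] *= 6
            M0[b, a] = M0[a, b]
    V = rng.lognormal(0, 0.25, n) * np.where(flags, 10.0, 1.0)

    def call_on(Vv, sample_seed, total=300_000):
        res = ipf_scale(M0, Vv)
        mat = rescale_total(res.matrix, total)
        sampler = np.random.default_rng(sample_seed + 1000)
        sampled = sampler.poisson(np.triu(mat, 1))
        cmap = matrix_to_contact_map(sampled, binsize, integerize=False)
        ann = BinAnnotation(binsize=binsize, n_bins={"chrSim": n})
        ann.peak_flags["chrSim"] = flags
        ann.coverage["chrSim"] = Vv * 100
        try:
            out = call_loops(
                cmap, ann, CallConfig(background="L", fdr=0.01, distance_high=1_000_000)
            )
            return len(out.loops)
        except ValueError:
            return 0

    n_real = call_on(V, seed)
    n_shuffled = [call_on(shuffle_coverage(V, s + seed), s + seed) for s in range(n_shuffles)]
    return n_real, n_shuffled
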