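"""B-allele-frequency cluster model shared by the simulator and the caller.

At a marker with population B-allele frequency ``p``, a sample carrying
``cn`` total copies holds ``b`` B alleles with ``b ~ Binomial(cn, p)``
(Hardy-Weinberg, independent allele draws), and its noise-free BAF sits at
``b / cn``.  Zero-copy markers have no allelic signal and emit uniform
noise on [0, 1].
"""

from __future__ import annotations

import numpy as np
from scipy import stats

#: cluster means per copy number: positions of b/cn for b = 0..cn
BAF_CLUSTERS = {
    1: np.array([0.0, 1.0]),
    2: np.array([0.0, 0.5, 1.0]),
    3: np.array([0.0, 1 / 3, 2 / 3, 1.0]),
    4: np.array([0.0, 0.25, 0.5, 0.75, 1.0]),
}


def genotype_weights(cn: int, pfb: np.ndarray) -> np.ndarray:
    """Binomial genotype probabilities, shape (n_markers, cn + 1)."""
    b = np.arange(cn + 1)
    return stats.binom.pmf(b[None, :], cn, np.asarray(pfb, float)[:, None])


def sample_baf(cn: int, pfb: np.ndarray, baf_sd: float, rng: np.random.Generator) -> np.ndarray:
    """Draw noisy BAF values for markers at copy number ``cn``."""
    pfb = np.asarray(pfb, float)
    if cn == 0:
        return rng.uniform(0.0, 1.0, size=pfb.shape)
    b = rng.binomial(cn, pfb)
    baf = b / cn + rng.normal(0.0, baf_sd, size=pfb.shape)
    return np.clip(baf, 0.0, 1.0)


def baf_loglik(baf: np.ndarray, cn: int, pfb: np.ndarray, baf_sd: float) -> np.ndarray:
    """Log density of observed BAF under the copy-number-``cn`` mixture.

    The Gaussian cluster jitter is evaluated without the boundary clipping
    mass — adequate for state discrimination, which is all the caller needs.
    """
    baf = np.asarray(baf, float)
    if cn == 0:
        return np.zeros_like(baf)  # uniform on [0, 1]
    clusters = BAF_CLUSTERS[cn]
    w = genotype_weights(cn, pfb)  # (n, cn+1)
    logpdf = stats.norm.logpdf(baf[:, None], loc=clusters[None, :], scale=baf_sd)
    with np.errstate(divide="ignore"):
        logw = np.log(w)
    m = np.max(logpdf + logw, axis=1)
    return m + np.log(np.sum(np.exp(logpdf + logw - m[:, None]), axis=1))
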