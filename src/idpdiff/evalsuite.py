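"""Ensemble-comparison metrics and the PCA landscape protocol.

Seven scores summarize how well a generated ensemble reproduces a reference
one, all computed from Cα geometry only:

========  ==========================================================
MSE_c     mean squared difference of contact-map probabilities
          (8 Å threshold, pairs with |i−j| ≥ 2)
MSE_d     mean squared difference of average pairwise distances (nm²)
aKLD_d    histogram KL divergence KL(ref ‖ gen), averaged over all
          pairwise-distance features
aKLD_t    same, over the L−3 α torsion features
KLD_r     KL(ref ‖ gen) of the radius-of-gyration distribution
aJSD_d    symmetric Jensen-Shannon counterpart of aKLD_d
aJSD_t    symmetric Jensen-Shannon counterpart of aKLD_t
========  ==========================================================

Divergences use natural logarithms, histogram estimators on the pooled
range of both sample sets, and a small pseudocount so empty bins do not
produce infinities.  The KL direction is reference-first, which penalizes
generated ensembles that miss reference modes.

The PCA landscape follows the standard protocol for conformational
free-energy surfaces: principal components of the reference ensemble's
pairwise-distance feature matrix, with the generated ensemble projected
onto the reference components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA

from .geometry import (
    Ensemble,
    InvalidInputError,
    alpha_torsions,
    contact_frequencies,
    pairwise_distances,
    radius_of_gyration,
)

ANGSTROM_TO_NM = 0.1


@dataclass
class HistogramSpec:
    """Binning policy for histogram divergence estimates."""

    bins_dist: int = 50
    bins_tors: int = 60
    bins_rg: int = 50
    pseudocount: float = 1e-9  # relative mass added to every bin
    min_separation: int = 2    # |i−j| ≥ 2 for pair-based scores

    def __post_init__(self):
        if min(self.bins_dist, self.bins_tors, self.bins_rg) < 2:
            raise InvalidInputError("need at least 2 bins")
        if self.pseudocount <= 0:
            raise InvalidInputError("pseudocount must be positive")


@dataclass
class EvalReport:
    MSE_c: float
    MSE_d: float          # nm²
    aKLD_d: float
    aKLD_t: float
    KLD_r: float
    aJSD_d: float
    aJSD_t: float
    metadata: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "MSE_c": self.MSE_c, "MSE_d": self.MSE_d,
            "aKLD_d": self.aKLD_d, "aKLD_t": self.aKLD_t,
            "KLD_r": self.KLD_r, "aJSD_d": self.aJSD_d,
            "aJSD_t": self.aJSD_t,
        }


def _check_pair(ref: Ensemble, gen: Ensemble) -> None:
    if ref.length != gen.length:
        raise InvalidInputError(
            f"ensembles have different lengths: {ref.length} vs {gen.length}")


def _offdiag_mask(L: int, min_sep: int) -> tuple[np.ndarray, np.ndarray]:
    iu, ju = np.triu_indices(L, min_sep)
    return iu, ju


def mse_c(ref: Ensemble, gen: Ensemble, threshold: float = 8.0,
          min_separation: int = 2) -> float:
    """Mean squared contact-probability difference over |i−j| ≥ 2 pairs."""
    _check_pair(ref, gen)
    pr = contact_frequencies(ref, threshold)
    pg = contact_frequencies(gen, threshold)
    iu, ju = _offdiag_mask(ref.length, min_separation)
    return float(np.mean((pr[iu, ju] - pg[iu, ju]) ** 2))


def mse_d(ref: Ensemble, gen: Ensemble, min_separation: int = 2) -> float:
    """Mean squared difference of average pairwise distances, in nm²."""
    _check_pair(ref, gen)
    dr = pairwise_distances(ref.coords).mean(axis=0) * ANGSTROM_TO_NM
    dg = pairwise_distances(gen.coords).mean(axis=0) * ANGSTROM_TO_NM
    iu, ju = _offdiag_mask(ref.length, min_separation)
    return float(np.mean((dr[iu, ju] - dg[iu, ju]) ** 2))


def _histograms(p_samples: np.ndarray, q_samples: np.ndarray, bins: int,
                value_range: tuple | None, pseudocount: float
                ) -> tuple[np.ndarray, np.ndarray] | None:
    if value_range is None:
        lo = min(p_samples.min(), q_samples.min())
        hi = max(p_samples.max(), q_samples.max())
        if hi <= lo:
            return None
        value_range = (lo, hi)
    hp, _ = np.histogram(p_samples, bins=bins, range=value_range)
    hq, _ = np.histogram(q_samples, bins=bins, range=value_range)
    p = hp + pseudocount * len(p_samples)
    q = hq + pseudocount * len(q_samples)
    return p / p.sum(), q / q.sum()


def histogram_divergence(samples_p, samples_q, bins: int = 50,
                         value_range: tuple | None = None,
                         pseudocount: float = 1e-9,
                         symmetric: bool = False) -> float:
    """Histogram estimate of KL(p‖q), or JSD(p,q) when ``symmetric``.

    Natural logarithm; samples are binned on the pooled range (or a fixed
    ``value_range``); every bin receives ``pseudocount`` relative mass.  If
    all samples coincide the divergence is 0 by convention (with a warning).
    """
    samples_p = np.asarray(samples_p, dtype=np.float64).ravel()
    samples_q = np.asarray(samples_q, dtype=np.float64).ravel()
    if samples_p.size == 0 or samples_q.size == 0:
        raise InvalidInputError("empty sample set")
    hists = _histograms(samples_p, samples_q, bins, value_range, pseudocount)
    if hists is None:
        warnings.warn("degenerate sample range; divergence set to 0")
        return 0.0
    p, q = hists
    if symmetric:
        m = 0.5 * (p + q)
        return float(0.5 * np.sum(p * np.log(p / m))
                     + 0.5 * np.sum(q * np.log(q / m)))
    return float(np.sum(p * np.log(p / q)))


def ensemble_report(ref: Ensemble, gen: Ensemble,
                    spec: HistogramSpec | None = None) -> EvalReport:
    """All seven comparison scores in one report."""
    spec = spec or HistogramSpec()
    _check_pair(ref, gen)
    L = ref.length
    iu, ju = _offdiag_mask(L, spec.min_separation)
    dr = pairwise_distances(ref.coords)[:, iu, ju]  # (N_ref, P)
    dg = pairwise_distances(gen.coords)[:, iu, ju]

    def avg_div(ps, qs, bins, symmetric, value_range=None):
        vals = [
            histogram_divergence(ps[:, j], qs[:, j], bins=bins,
                                 value_range=value_range,
                                 pseudocount=spec.pseudocount,
                                 symmetric=symmetric)
            for j in range(ps.shape[1])
        ]
        return float(np.mean(vals))

    tr = alpha_torsions(ref.coords)
    tg = alpha_torsions(gen.coords)
    rg_r = radius_of_gyration(ref.coords)
    rg_g = radius_of_gyration(gen.coords)
    report = EvalReport(
        MSE_c=mse_c(ref, gen, min_separation=spec.min_separation),
        MSE_d=mse_d(ref, gen, min_separation=spec.min_separation),
        aKLD_d=avg_div(dr, dg, spec.bins_dist, False),
        aKLD_t=avg_div(tr, tg, spec.bins_tors, False, (-180.0, 180.0)),
        KLD_r=histogram_divergence(rg_r, rg_g, bins=spec.bins_rg,
                                   pseudocount=spec.pseudocount),
        aJSD_d=avg_div(dr, dg, spec.bins_dist, True),
        aJSD_t=avg_div(tr, tg, spec.bins_tors, True, (-180.0, 180.0)),
        metadata={"n_ref": ref.n_members, "n_gen": gen.n_members,
                  "L": L, "min_separation": spec.min_separation},
    )
    return report


@dataclass
class PCALandscape:
    components: np.ndarray        # (n_components, P) loadings, orthonormal
    explained_variance: np.ndarray
    ref_projection: np.ndarray    # (N_ref, n_components)
    gen_projection: np.ndarray    # (N_gen, n_components)
    feature_pairs: np.ndarray     # (P, 2) residue indices of each feature
    top_loading_features: np.ndarray  # per component, index into feature_pairs


def pca_landscape(ref: Ensemble, gen: Ensemble, n_components: int = 5,
                  min_separation: int = 2) -> PCALandscape:
    """PCA of the reference distance features; generated ensemble projected.

    Features are all pairwise distances with |i−j| ≥ ``min_separation``,
    centered but not scaled.  The per-component feature with the highest
    absolute loading identifies the distance dominating that component.
    """
    _check_pair(ref, gen)
    if ref.n_members < n_components + 1:
        raise InvalidInputError(
            f"reference has {ref.n_members} members; PCA with "
            f"{n_components} components needs at least {n_components + 1}")
    iu, ju = _offdiag_mask(ref.length, min_separation)
    Xr = pairwise_distances(ref.coords)[:, iu, ju]
    Xg = pairwise_distances(gen.coords)[:, iu, ju]
    pca = PCA(n_components=n_components)
    proj_r = pca.fit_transform(Xr)
    proj_g = pca.transform(Xg)
    return PCALandscape(
        components=pca.components_,
        explained_variance=pca.explained_variance_,
        ref_projection=proj_r,
        gen_projection=proj_g,
        feature_pairs=np.stack([iu, ju], axis=1),
        top_loading_features=np.argmax(np.abs(pca.components_), axis=1),
    )
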