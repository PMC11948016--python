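"""Shared fixtures-in-code and independent oracles for the test suite.

The oracles here are deliberately independent of the implementation
paths they check (direct master-equation integration, closed-form
moments, brute-force sums), so a regression in the package cannot hide
inside its own test harness.
"""

from __future__ import annotations

import numpy as np
from scipy import integrate

from lipoclust import image_quant as iq
from lipoclust import synthetic_data as sd

HIGH_SNR = sd.NoiseModel(background_level=0.0, gaussian_read_noise_sd=1.0)
DEFAULT_NOISE = sd.NoiseModel()  # 100-photon background, shot + read noise
SPARSE_PARAMS = iq.PreprocessParams(threshold_method="triangle")


def quantify_scene(scene, noise=HIGH_SNR, params=SPARSE_PARAMS, seed=0):
    """Render the liposome channel, segment, and measure all features."""
    frame = sd.render_frame(scene, "liposome", noise, seed)
    filtered = iq.preprocess_liposome_channel(frame, params)
    labels = iq.segment(filtered, params)
    return iq.measure_all(labels, frame), frame


def measured_truth_table(size_lists, morphology, seed0=0, noise=HIGH_SNR,
                         params=SPARSE_PARAMS, flux=20000.0,
                         field=(512, 512), target_df=1.6):
    """Render batches of prescribed cluster sizes; return matched truth rows."""
    import pandas as pd

    rng = np.random.default_rng(seed0)
    tables = []
    for batch in size_lists:
        scene = sd.scene_from_sizes(batch, field_shape=field,
                                    morphology=morphology, target_df=target_df,
                                    flux_liposome=flux, flux_rna=0.0,
                                    seed=rng)
        feats, _ = quantify_scene(scene, noise, params,
                                  seed=int(rng.integers(2 ** 31)))
        tables.append(sd.match_features_to_truth(feats, scene))
    return pd.concat(tables, ignore_index=True)


def birth_process_pmf(rate_rule: str, lam: float, t: float,
                      kmax: int = 200) -> np.ndarray:
    """Master-equation oracle for the adsorption birth process.

    Integrates dP_k/dt = lam * (w_{k-1} P_{k-1} - w_k P_k) with
    w_k = k+1 (linear rule) or w_k = 1 (constant rule) from P = delta_0,
    over k = 0..kmax.  Independent of the Gillespie simulation path.
    """
    w = (np.arange(kmax + 1) + 1.0) if rate_rule == "linear" else np.ones(kmax + 1)

    def rhs(_t, p):
        dp = -lam * w * p
        dp[1:] += lam * w[:-1] * p[:-1]
        return dp

    p0 = np.zeros(kmax + 1)
    p0[0] = 1.0
    sol = integrate.solve_ivp(rhs, (0.0, t), p0, rtol=1e-10, atol=1e-14,
                              method="LSODA")
    p = np.clip(sol.y[:, -1], 0.0, None)
    return p / p.sum()


def geometric_pmf(mean: float, kmax: int) -> np.ndarray:
    """Closed-form geometric law on {0..kmax} (tail not folded)."""
    q = mean / (1.0 + mean)
    n = np.arange(kmax + 1)
    return (1.0 / (1.0 + mean)) * q ** n


def chi2_gof_pvalue(counts: np.ndarray, pmf: np.ndarray,
                    min_expected: float = 5.0) -> float:
    """Chi-square goodness of fit with tail pooling (independent check)."""
    from scipy import stats

    n = counts.sum()
    kmax = max(counts.size, pmf.size)
    obs = np.zeros(kmax)
    obs[:counts.size] = counts
    exp = np.zeros(kmax)
    exp[:pmf.size] = pmf * n
    exp[-1] += n - exp.sum()          # fold residual tail mass
    # pool bins from the right until every expected count is large enough
    while exp.size > 2 and exp[-1] < min_expected:
        exp[-2] += exp[-1]
        obs[-2] += obs[-1]
        exp, obs = exp[:-1], obs[:-1]
    stat = ((obs - exp) ** 2 / exp).sum()
    dof = exp.size - 1
    return float(stats.chi2.sf(stat, dof))
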