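"""Bayesian single step-change detection in intensity series.

Sudden shifts in scene illumination (lights switched on/off, shadows)
appear as steps in the raw PPGi series. The model is two piecewise-constant
levels with Gaussian noise; with flat priors on the two means and the noise
scale marginalised out, the posterior over the step location m reduces to a
closed form involving only the within-segment sums of squares. The
proportionality is normalised over the admissible locations
m in [2, N-2] (at least two samples per segment) so that a probability
threshold on the posterior is well defined. Evaluation is done in log
space: the bracket term is raised to the power -(N-2)/2, which overflows
immediately for windows of a few hundred samples otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_LOG_EPS = 1e-300


@dataclass
class ChangePointResult:
    window_start: int        # sample offset of the window in the session
    posterior: np.ndarray    # probability per split m (index 0 -> m=2)
    m_values: np.ndarray     # candidate split locations (1-based counts)
    p_max: float
    m_hat: int               # argmax split: first 0-based sample of the new level
    no_evidence: bool = False

    def sample_probabilities(self, n: int) -> np.ndarray:
        """Posterior mass mapped onto 0-based sample indices of the window."""
        p = np.zeros(n)
        p[self.m_values] = self.posterior  # step sits at sample index m
        return p


def step_log_posterior(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unnormalised log posterior over split locations m in [2, N-2].

    Split m means samples 1..m (1-based) belong to the first level and
    m+1..N to the second. Returns (m_values, log_posterior).
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 8:
        raise ValueError("need at least 8 samples")
    m = np.arange(2, n - 1)  # inclusive of N-2
    csum = np.cumsum(x)
    csq = np.cumsum(x * x)
    total_sq = csq[-1]
    s1 = csum[m - 1]
    s2 = csum[-1] - s1
    bracket = total_sq - s1 * s1 / m - s2 * s2 / (n - m)
    bracket = np.maximum(bracket, _LOG_EPS)
    logp = -0.5 * np.log(m * (n - m)) - 0.5 * (n - 2) * np.log(bracket)
    return m, logp


def step_posterior(x: np.ndarray, window_start: int = 0) -> ChangePointResult:
    """Normalised posterior over the location of a single step change.

    A constant window carries no evidence for any location; it is flagged
    and assigned a uniform posterior.
    """
    x = np.asarray(x, dtype=float)
    m, logp = step_log_posterior(x)
    no_evidence = bool(np.ptp(x) == 0.0)
    if no_evidence:
        post = np.full(len(m), 1.0 / len(m))
    else:
        logp = logp - logp.max()
        post = np.exp(logp)
        post /= post.sum()
    k = int(np.argmax(post))
    return ChangePointResult(
        window_start=window_start,
        posterior=post,
        m_values=m,
        p_max=float(post[k]),
        m_hat=int(m[k]),
        no_evidence=no_evidence,
    )


def scan_changepoints(
    series: np.ndarray,
    fps: float,
    window_s: float = 30.0,
    hop_s: float = 25.0,
) -> np.ndarray:
    """Per-sample step probability over a whole series.

    The single-step posterior is evaluated on running windows (default 30 s
    span advancing 25 s, i.e. 5-s overlap); each sample's probability is
    the maximum posterior mass assigned to it by any covering window.
    Returns an array the length of the series (empty-window remainder gets
    zeros); raises if the series is shorter than one window.
    """
    x = np.asarray(series, dtype=float)
    wlen = int(round(window_s * fps))
    hop = max(1, int(round(hop_s * fps)))
    if len(x) < wlen:
        raise ValueError("series shorter than one change-point window")
    prob = np.zeros(len(x))
    starts = list(range(0, len(x) - wlen + 1, hop))
    if starts[-1] != len(x) - wlen:
        starts.append(len(x) - wlen)  # cover the tail
    for s in starts:
        res = step_posterior(x[s : s + wlen], window_start=s)
        if res.no_evidence:
            continue
        p = res.sample_probabilities(wlen)
        np.maximum(prob[s : s + wlen], p, out=prob[s : s + wlen])
    return prob
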