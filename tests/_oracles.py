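"""Independent reference implementations used only to check seasonwave.

These deliberately take the slow, direct route (time-domain convolution,
label permutation) so they share no code path with the implementations
they validate.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

from seasonwave.wavelet import fourier_factor


def cwt_direct_convolution(
    x: np.ndarray, periods: np.ndarray, omega0: float = 6.0
) -> np.ndarray:
    """Direct time-domain Morlet CWT via explicit kernel convolution.

    The analytic kernel matching the frequency-domain filter
    ``2 exp(-(s w - w0)^2 / 2)`` (positive frequencies) is

        h_s(tau) = sqrt(2/pi) / s * exp(i w0 tau / s) * exp(-tau^2 / (2 s^2)),

    truncated at ``|tau| <= 10 s``. Valid for scales whose pass band lies
    well below the Nyquist frequency (period >> 2 weeks).
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    out = np.empty((len(periods), n), dtype=complex)
    for i, p in enumerate(periods):
        s = p / fourier_factor(omega0)
        half = int(np.ceil(10 * s))
        tau = np.arange(-half, half + 1, dtype=float)
        kernel = (
            np.sqrt(2.0 / np.pi)
            / s
            * np.exp(1j * omega0 * tau / s)
            * np.exp(-(tau**2) / (2 * s**2))
        )
        # full convolution, then take the n samples aligned with the input
        # (kernel index tau = 0 sits at array position ``half``)
        out[i] = np.convolve(x, kernel, mode="full")[half : half + n]
    return out


def tukey_permutation_pvalue(
    groups: dict[str, np.ndarray],
    pair: tuple[str, str],
    n_permutations: int = 10_000,
    seed: int = 0,
) -> float:
    """Permutation reference for a Tukey HSD adjusted p-value.

    The familywise-adjusted p for a pair equals the null probability that
    the *maximum* pairwise studentized-range statistic exceeds the pair's
    observed statistic; here that null is approximated by re-computing the
    max-q statistic over random relabelings of the pooled observations.
    """
    names = list(groups)
    sizes = [len(groups[k]) for k in names]
    pooled = np.concatenate([np.asarray(groups[k], float) for k in names])

    def max_q_and_pair_q(values_by_group):
        df_within = sum(len(v) - 1 for v in values_by_group.values())
        ms_within = (
            sum(((v - v.mean()) ** 2).sum() for v in values_by_group.values())
            / df_within
        )
        qs = {}
        for a, b in combinations(values_by_group, 2):
            va, vb = values_by_group[a], values_by_group[b]
            se = np.sqrt(ms_within / 2 * (1 / len(va) + 1 / len(vb)))
            qs[(a, b)] = abs(va.mean() - vb.mean()) / se
        return max(qs.values()), qs

    _, observed_qs = max_q_and_pair_q(
        {k: np.asarray(v, float) for k, v in groups.items()}
    )
    q_obs = observed_qs[pair] if pair in observed_qs else observed_qs[pair[::-1]]

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(pooled)
        regrouped = {}
        start = 0
        for name, size in zip(names, sizes):
            regrouped[name] = perm[start : start + size]
            start += size
        max_q, _ = max_q_and_pair_q(regrouped)
        if max_q >= q_obs:
            count += 1
    return (1 + count) / (n_permutations + 1)
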