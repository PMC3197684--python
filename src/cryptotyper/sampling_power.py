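"""Detection probability for a rare genotype in a finite sample.

When every individual genotyped at a locality belongs to one genotype, how
abundant could an undetected second genotype still be? With ``p`` the
relative abundance of the rare genotype and ``N`` the number of collected
individuals, the probability of having collected none of them is

    q = (1 - p) ** N

and the largest abundance still consistent with observing none, at
confidence level ``c``, is

    p_max = 1 - (1 - c) ** (1 / N).

These bounds justify treating non-genotyped specimens collected on one side
of a hydrographic front as a single-genotype population.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


class SamplingPowerError(ValueError):
    pass


def miss_probability(p, N):
    """Probability q = (1 - p)**N of not collecting the rare genotype.

    Accepts scalars or arrays; p must lie in [0, 1] and N be >= 1.
    """
    p = np.asarray(p, dtype=float)
    N = np.asarray(N)
    if np.any((p < 0) | (p > 1)):
        raise SamplingPowerError("p must lie in [0, 1]")
    if np.any(N < 1):
        raise SamplingPowerError("N must be >= 1")
    q = (1.0 - p) ** N
    return float(q) if q.ndim == 0 else q


def undetected_fraction(N, confidence: float = 0.95):
    """Largest rare-genotype abundance p_max consistent, at the stated
    confidence, with observing none of it among N sampled individuals."""
    N = np.asarray(N)
    if np.any(N < 1):
        raise SamplingPowerError("N must be >= 1")
    if not 0 < confidence < 1:
        raise SamplingPowerError("confidence must lie in (0, 1)")
    p = 1.0 - (1.0 - confidence) ** (1.0 / N)
    return float(p) if p.ndim == 0 else p


def station_report(stations, confidence: float = 0.95) -> pd.DataFrame:
    """Per-station and pooled-side detection bounds.

    For each station with genotyped individuals the table carries N, the
    observed genotype and p_max; two pooled rows aggregate all stations of
    each side of the front. Stations with N = 0 are skipped. The row with
    the overall largest p_max is flagged (the weakest link of the
    single-genotype assumption).
    """
    rows = []
    pooled: dict[str, int] = {}
    for s in stations:
        n = s.n_genotyped
        if n == 0:
            continue
        observed = "+".join(g for g in ("I", "II") if s.count(g) > 0) or "none"
        rows.append(
            {
                "station_id": s.station_id,
                "side": s.side,
                "N": n,
                "observed_genotype": observed,
                "p_max": undetected_fraction(n, confidence),
            }
        )
        if s.side:
            pooled[s.side] = pooled.get(s.side, 0) + n
    for side, n in sorted(pooled.items()):
        rows.append(
            {
                "station_id": f"pooled_{side}",
                "side": side,
                "N": n,
                "observed_genotype": "pooled",
                "p_max": undetected_fraction(n, confidence),
            }
        )
    if not rows:
        raise SamplingPowerError("no station carries genotyped individuals")
    df = pd.DataFrame(rows)
    df["flagged_max"] = df["p_max"] == df["p_max"].max()
    return df
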