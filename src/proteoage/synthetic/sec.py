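"""Synthetic SEC-MS co-fractionation profiles.

Members of a complex share a Gaussian elution apex (plus small member
jitter); injected shifts displace the old-condition apex of selected
complexes toward later fractions (lower apparent mass). Non-member
proteins elute at independent apexes identical across conditions.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from ..containers import ComplexCatalog, SECMatrix
from .truth import SyntheticTruth


def generate_sec_profiles(
    catalog: ComplexCatalog,
    n_fractions: int = 39,
    shifts: dict | None = None,
    noise_sd: float = 0.05,
    member_jitter_sd: float = 0.4,
    n_free_proteins: int = 200,
    seed: int = 0,
) -> tuple[SECMatrix, SECMatrix, SyntheticTruth]:
    """Generate young- and old-condition SEC matrices.

    ``shifts`` maps complex ids (must exist in the catalog) to apex
    offsets in fractions applied in the old condition; apexes pushed
    outside [1, n_fractions] are clipped with a warning. ``noise_sd`` is
    additive Gaussian noise relative to the unit peak height.
    """
    shifts = dict(shifts or {})
    unknown = set(shifts) - set(catalog.names())
    if unknown:
        raise ValueError(f"shifts reference unknown complexes: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    fractions = np.arange(1, n_fractions + 1, dtype=float)

    complex_apex = {
        name: float(rng.uniform(5, n_fractions - 5)) for name in catalog.names()
    }
    rows_young, rows_old, index = [], [], []

    def peak(apex, width, amplitude, jitter=0.0):
        clean = amplitude * np.exp(-((fractions - apex - jitter) ** 2) / (2 * width**2))
        noisy = clean + rng.normal(0.0, noise_sd * amplitude, n_fractions)
        return np.clip(noisy, 0.0, None)

    seen = set()
    for name in catalog.names():
        apex = complex_apex[name]
        shift = shifts.get(name, 0.0)
        shifted = apex + shift
        if not 1 <= shifted <= n_fractions:
            warnings.warn(
                f"complex {name}: shifted apex {shifted:.1f} outside "
                f"[1, {n_fractions}], clipped",
                RuntimeWarning,
            )
            shifted = float(np.clip(shifted, 1, n_fractions))
        width = float(rng.uniform(1.2, 2.2))
        for member in sorted(catalog.members(name)):
            if member in seen:  # protein already placed by another complex
                continue
            seen.add(member)
            amplitude = float(rng.lognormal(0.0, 0.4))
            jitter = float(rng.normal(0.0, member_jitter_sd))
            index.append(member)
            rows_young.append(peak(apex, width, amplitude, jitter))
            rows_old.append(peak(shifted, width, amplitude, jitter))

    for i in range(n_free_proteins):
        apex = float(rng.uniform(1, n_fractions))
        width = float(rng.uniform(1.2, 3.0))
        amplitude = float(rng.lognormal(0.0, 0.4))
        index.append(f"FREE{i + 1:04d}")
        rows_young.append(peak(apex, width, amplitude))
        rows_old.append(peak(apex, width, amplitude))

    columns = np.arange(1, n_fractions + 1)
    young = SECMatrix(
        pd.DataFrame(rows_young, index=index, columns=columns),
        condition="young",
        replicate="1",
    )
    old = SECMatrix(
        pd.DataFrame(rows_old, index=index, columns=columns),
        condition="old",
        replicate="1",
    )
    truth = SyntheticTruth(
        seed=seed,
        complex_apex=complex_apex,
        sec_shifts={k: float(v) for k, v in shifts.items()},
    )
    return young, old, truth
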