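"""Optical constants and the Beer-Lambert forward model.

Extinction coefficients are a compiled standard tabulation of hemoglobin
molar extinction (Prahl-type values, cm^-1 / (mol/L)), converted here to
1/(uM*cm) so that concentrations are expressed in micromolar.  The
differential pathlength factor (DPF) scales the geometric source-detector
distance to the effective photon path length; 6.0 is a conventional adult
value at these wavelengths.
"""

from __future__ import annotations

import numpy as np

#: Molar extinction, 1/(uM*cm), keyed by wavelength (nm): (HbO, HbR).
EXTINCTION_UM_CM: dict[float, tuple[float, float]] = {
    760.0: (586.0e-6, 1548.52e-6),
    850.0: (1058.0e-6, 691.32e-6),
}

#: Default differential pathlength factor per wavelength.
DEFAULT_DPF: tuple[float, float] = (6.0, 6.0)


def extinction_matrix(wavelengths) -> np.ndarray:
    """Return the (n_wavelengths, 2) extinction matrix [[e_HbO, e_HbR], ...]."""
    rows = []
    for wl in wavelengths:
        if float(wl) not in EXTINCTION_UM_CM:
            raise ValueError(
                f"no tabulated extinction coefficients for {wl} nm; "
                f"known wavelengths: {sorted(EXTINCTION_UM_CM)}"
            )
        rows.append(EXTINCTION_UM_CM[float(wl)])
    return np.asarray(rows, dtype=float)


def forward_optical_density(
    dHbO: np.ndarray,
    dHbR: np.ndarray,
    wavelengths=(760.0, 850.0),
    dpf=DEFAULT_DPF,
    distance: float = 3.0,
    extinction: np.ndarray | None = None,
) -> np.ndarray:
    """Compose optical-density changes from concentration changes.

    dOD_lambda(t) = d * DPF_lambda * (e_HbO * dHbO(t) + e_HbR * dHbR(t))

    Parameters
    ----------
    dHbO, dHbR : (channels, samples) concentration changes in uM.
    distance : source-detector separation in cm.

    Returns
    -------
    (channels, n_wavelengths, samples) optical-density changes.
    """
    if distance <= 0:
        raise ValueError("distance must be > 0")
    eps = extinction_matrix(wavelengths) if extinction is None else np.asarray(extinction)
    dpf = np.asarray(dpf, dtype=float)
    if eps.shape[0] != dpf.shape[0]:
        raise ValueError("dpf length must match the number of wavelengths")
    conc = np.stack([dHbO, dHbR], axis=1)  # (C, 2, T)
    od = np.einsum("wk,ckt->cwt", eps, conc)
    return distance * dpf[None, :, None] * od
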