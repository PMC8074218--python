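"""Encapsulation response variables for spray-dried microparticles.

Three standard figures of merit quantify how well a spray-drying run
encapsulated its phenolic core:

* encapsulation yield (EY) — powder recovered as a percent of solids fed;
* loading capacity (LC) — entrapped phenolics (total minus surface) per
  100 g of powder;
* encapsulation efficiency (EE) — entrapped phenolics as a percent of the
  theoretical phenolic content of the formulation.

Phenolic contents are expressed in g per 100 g of microparticles, so LC is
simply ``total - surface``. The theoretical phenolic content used in the EE
denominator is the core mass fraction of total solids times 100: the tannin
extract core is treated as entirely phenolic. Under this convention
``LC = EE * core_fraction`` is an algebraic identity.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "encapsulation_yield",
    "loading_capacity",
    "theoretical_phenolic_content",
    "encapsulation_efficiency",
    "compute_response_table",
]


def _asarray(*vals):
    arrs = np.broadcast_arrays(*[np.asarray(v, dtype=float) for v in vals])
    return arrs


def encapsulation_yield(powder_collected, solids_fed):
    """Percent of solids fed to the dryer recovered as powder.

    ``100 * powder_collected / solids_fed``; both in the same mass unit.
    """
    powder, solids = _asarray(powder_collected, solids_fed)
    if np.any(solids <= 0):
        raise ValueError("solids_fed must be positive")
    if np.any(powder < 0):
        raise ValueError("powder_collected must be non-negative")
    out = 100.0 * powder / solids
    return out if out.ndim else float(out)


def loading_capacity(total_phenolics, surface_phenolics):
    """Entrapped phenolics per 100 g of microparticles.

    With both contents already expressed in g/100 g of powder, the
    per-particle-mass normalization is the identity and LC reduces to
    ``total - surface``.
    """
    total, surface = _asarray(total_phenolics, surface_phenolics)
    if np.any(surface > total):
        raise ValueError("surface phenolic content exceeds total phenolic content")
    out = total - surface
    return out if out.ndim else float(out)


def theoretical_phenolic_content(core_mass, shell_mass):
    """Core mass fraction of total solids, times 100 (g/100 g powder).

    The phenolic-rich core is treated as 100% phenolics, so a formulation
    with core:shell mass ratio c:s could at most carry ``100*c/(c+s)`` g of
    phenolics per 100 g of powder.
    """
    core, shell = _asarray(core_mass, shell_mass)
    if np.any(core < 0) or np.any(shell < 0):
        raise ValueError("masses must be non-negative")
    denom = core + shell
    if np.any(denom <= 0):
        raise ValueError("core_mass + shell_mass must be positive")
    out = 100.0 * core / denom
    return out if out.ndim else float(out)


def encapsulation_efficiency(total_phenolics, surface_phenolics, core_mass, shell_mass):
    """Entrapped phenolics as percent of the theoretical phenolic content."""
    entrapped = loading_capacity(total_phenolics, surface_phenolics)
    theoretical = theoretical_phenolic_content(core_mass, shell_mass)
    if np.any(np.asarray(theoretical) <= 0):
        raise ValueError("theoretical phenolic content is zero (no core material)")
    out = 100.0 * np.asarray(entrapped) / np.asarray(theoretical)
    return out if out.ndim else float(out)


def compute_response_table(measurements: pd.DataFrame) -> pd.DataFrame:
    """Derive EY/EE/LC columns from per-run measurements.

    Expects columns ``run_id``, ``tpc_total``, ``tpc_surface``,
    ``core_mass``, ``shell_mass`` and optionally ``powder_collected`` /
    ``solids_fed`` (for EY). Any other columns are carried through
    untouched (moisture, water activity, color and similar passthrough
    data are never modeled).
    """
    out = measurements.copy()
    out["lc"] = loading_capacity(out["tpc_total"], out["tpc_surface"])
    out["ee"] = encapsulation_efficiency(
        out["tpc_total"], out["tpc_surface"], out["core_mass"], out["shell_mass"]
    )
    if {"powder_collected", "solids_fed"} <= set(out.columns):
        out["ey"] = encapsulation_yield(out["powder_collected"], out["solids_fed"])
    return out
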