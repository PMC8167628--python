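"""Sensitivity of the calculated volume to misspecified reference
densities.

The mixture inversion uses two reference densities; if either is wrong
by a few HU (miscalibration, scanner drift, kernel-induced shifts), the
calculated volume shifts.  This module reruns the volume computation on
the *recorded* per-slice measurements with offset references and
reports the percent change, over the four scenario classes: only the
object density offset, only the background density offset, both offset
with opposite signs, and both with the same sign.

Because the offsets enter a closed-form expression, every grid entry
has an exact oracle; no re-simulation is involved.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .volumetry import MaterialPair, SliceROIMeasurement, total_volume

__all__ = [
    "SCENARIO_CLASSES",
    "DEFAULT_DELTAS_HU",
    "PerturbationScenario",
    "SensitivityResult",
    "perturbed_volume",
    "scenario_grid",
    "results_to_dataframe",
    "save_grid_csv",
    "plot_grid",
]

SCENARIO_CLASSES = ("object_only", "background_only", "opposite_sign",
                    "same_sign")

#: HU offsets evaluated by default (applied with both signs).
DEFAULT_DELTAS_HU = (2.0, 5.0, 10.0)


def classify(delta_object: float, delta_background: float) -> str:
    if delta_object == 0 and delta_background == 0:
        return "null"
    if delta_background == 0:
        return "object_only"
    if delta_object == 0:
        return "background_only"
    return "opposite_sign" if delta_object * delta_background < 0 else "same_sign"


@dataclass(frozen=True)
class PerturbationScenario:
    """HU offsets applied to the two reference densities."""

    delta_object: float
    delta_background: float
    scenario_class: Optional[str] = None

    def __post_init__(self) -> None:
        derived = classify(self.delta_object, self.delta_background)
        if self.scenario_class is None:
            object.__setattr__(self, "scenario_class", derived)
        elif self.scenario_class != derived:
            raise ValueError(
                f"scenario_class {self.scenario_class!r} inconsistent with "
                f"deltas ({self.delta_object}, {self.delta_background}); "
                f"expected {derived!r}")


@dataclass(frozen=True)
class SensitivityResult:
    scenario: PerturbationScenario
    volume_cm3: float
    pct_change: float


def perturbed_volume(
    measurements: Sequence[SliceROIMeasurement],
    materials: MaterialPair,
    slice_thickness_mm: float,
    scenario: PerturbationScenario,
) -> SensitivityResult:
    """Volume recomputed with offset reference densities, plus the
    percent change relative to the unperturbed volume."""
    new_contrast = (materials.contrast + scenario.delta_object
                    - scenario.delta_background)
    if abs(new_contrast) <= 1e-9 * max(1.0, abs(materials.contrast)):
        raise ValueError(
            f"perturbation ({scenario.delta_object}, "
            f"{scenario.delta_background}) collapses the two reference "
            "densities")
    perturbed = materials.shifted(scenario.delta_object,
                                  scenario.delta_background)
    base = total_volume(measurements, materials, slice_thickness_mm)
    new = total_volume(measurements, perturbed, slice_thickness_mm)
    pct = 100.0 * (new.total_volume_cm3 / base.total_volume_cm3 - 1.0)
    return SensitivityResult(scenario=scenario,
                             volume_cm3=new.total_volume_cm3,
                             pct_change=pct)


def scenario_grid(
    measurements: Sequence[SliceROIMeasurement],
    materials: MaterialPair,
    slice_thickness_mm: float,
    deltas: Iterable[float] = DEFAULT_DELTAS_HU,
) -> list[SensitivityResult]:
    """Evaluate all four scenario classes at every signed offset.

    For offsets d in ``deltas`` and both signs s: object_only (sd, 0),
    background_only (0, sd), opposite_sign (sd, -sd), same_sign
    (sd, sd) — 4 x 2 x len(deltas) results (24 for the default three
    offsets).
    """
    deltas = sorted({abs(float(d)) for d in deltas})
    if not deltas or deltas[0] == 0:
        raise ValueError("deltas must be nonempty and nonzero")
    results = []
    for d in deltas:
        for s in (+1.0, -1.0):
            for do, dj in ((s * d, 0.0), (0.0, s * d),
                           (s * d, -s * d), (s * d, s * d)):
                scen = PerturbationScenario(do, dj)
                results.append(perturbed_volume(
                    measurements, materials, slice_thickness_mm, scen))
    return results


def results_to_dataframe(results: Iterable[SensitivityResult]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "scenario_class": r.scenario.scenario_class,
            "delta_object": r.scenario.delta_object,
            "delta_background": r.scenario.delta_background,
            "volume_cm3": r.volume_cm3,
            "pct_change": r.pct_change,
        }
        for r in results
    ])


def save_grid_csv(results: Iterable[SensitivityResult], path) -> None:
    results_to_dataframe(results).to_csv(path, index=False)


def plot_grid(results: Iterable[SensitivityResult], path=None):
    """Four-panel scatter of percent volume change vs HU offset, one
    panel per scenario class."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = results_to_dataframe(results)
    fig, axes = plt.subplots(2, 2, figsize=(9, 7), sharey=True)
    for ax, cls in zip(axes.ravel(), SCENARIO_CLASSES):
        sub = df[df["scenario_class"] == cls]
        x = np.where(sub["scenario_class"] == "background_only",
                     sub["delta_background"], sub["delta_object"])
        ax.scatter(x, sub["pct_change"])
        ax.axhline(0, color="0.7", lw=0.8)
        ax.set_title(cls.replace("_", " "))
        ax.set_xlabel("ΔHU")
    for ax in axes[:, 0]:
        ax.set_ylabel("volume change (%)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
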