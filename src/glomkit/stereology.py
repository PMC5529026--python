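"""Weibel-Gomez stereology: podocyte number per glomerulus from 2D profiles.

Model-based stereology converts measurements made on random planar sections
of glomeruli — the number of WT-1⁺ (podocyte) nuclear profiles per tuft and
the WT-1-stained areal fraction — into three-dimensional quantities:

* numerical density of podocyte nuclei per unit glomerular volume,
  ``N_V = (K/β) · sqrt(N_A³ / A_A)``,
* glomerular volume from the mean tuft profile area,
  ``V_glom = mean_area^1.5 · β/K``,
* and their product, the estimated podocyte number per glomerulus.

The shape coefficient β encodes particle geometry (β = sqrt(6/π) ≈ 1.382 for
a sphere) and the distribution coefficient K the spread of particle sizes
(K = 1 for monodisperse particles).  The default coefficients are the values
conventionally used for podocyte nuclei (K = 1.1, β = 1.45) and for the
glomerulus treated as a sphere with a narrow size distribution
(β = 1.38, K = 1.01).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "GlomerularProfile",
    "StereologyCoefficients",
    "PodocyteEstimate",
    "ProfileSummary",
    "DEFAULT_COEFFICIENTS",
    "SPHERE_COEFFICIENTS",
    "profile_summary",
    "nv_weibel_gomez",
    "vglom_weibel_gomez",
    "npod_glom",
    "estimate_podocytes",
    "estimate_by_animal",
]


@dataclass(frozen=True)
class GlomerularProfile:
    """Measurements on one 2D glomerular cross-sectional profile.

    Areas are in μm²; ``n_wt1`` is the count of WT-1⁺ nuclear profiles
    within the tuft.  Collagen-IV and PAS stain areas are optional extra
    channels used by the morphometry stage.
    """

    tuft_area: float
    n_wt1: int
    wt1_stain_area: float
    colIV_area: float | None = None
    pas_area: float | None = None
    glom_id: str | None = None
    section_id: str | None = None

    def __post_init__(self) -> None:
        if self.tuft_area <= 0:
            raise ValueError(f"tuft_area must be positive, got {self.tuft_area}")
        if self.n_wt1 < 0:
            raise ValueError("n_wt1 must be non-negative")
        if self.wt1_stain_area < 0 or self.wt1_stain_area > self.tuft_area:
            raise ValueError("wt1_stain_area must lie in [0, tuft_area]")
        if self.n_wt1 == 0 and self.wt1_stain_area != 0:
            raise ValueError("wt1_stain_area must be 0 when n_wt1 is 0")


@dataclass(frozen=True)
class StereologyCoefficients:
    """Shape (β) and size-distribution (K) coefficients for the two steps."""

    k_nuc: float = 1.1
    beta_nuc: float = 1.45
    beta_glom: float = 1.38
    k_glom: float = 1.01

    def __post_init__(self) -> None:
        for name in ("k_nuc", "beta_nuc", "beta_glom", "k_glom"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


#: Conventional coefficients for podocyte nuclei / glomeruli.
DEFAULT_COEFFICIENTS = StereologyCoefficients()

#: Exact coefficients for monodisperse spheres (β = sqrt(6/π) ≈ 1.382, K = 1);
#: with these the estimator chain is unbiased on ideal spherical geometry.
SPHERE_COEFFICIENTS = StereologyCoefficients(
    k_nuc=1.0, beta_nuc=1.382, beta_glom=1.382, k_glom=1.0
)


class ProfileSummary(NamedTuple):
    n_a: float
    a_a: float
    mean_tuft_area: float
    mean_nuclear_size: float  # NaN when no nucleus was counted
    n_profiles: int


@dataclass(frozen=True)
class PodocyteEstimate:
    """Full Weibel-Gomez output chain for one animal or cohort."""

    n_a: float
    a_a: float
    n_v: float
    v_glom: float
    n_pod: float
    density: float  # podocytes per 10^6 μm³
    mean_nuclear_size: float  # μm² per WT-1⁺ nucleus; NaN when count is 0
    n_profiles: int


def _as_frame(profiles: Iterable[GlomerularProfile] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(profiles, pd.DataFrame):
        df = profiles.rename(
            columns={"tuft_area_um2": "tuft_area", "wt1_area_um2": "wt1_stain_area"}
        )
        missing = {"tuft_area", "n_wt1", "wt1_stain_area"} - set(df.columns)
        if missing:
            raise ValueError(f"profile table missing columns: {sorted(missing)}")
        return df
    rows = list(profiles)
    if rows and not isinstance(rows[0], GlomerularProfile):
        raise TypeError("expected GlomerularProfile instances or a DataFrame")
    return pd.DataFrame(
        {
            "tuft_area": [p.tuft_area for p in rows],
            "n_wt1": [p.n_wt1 for p in rows],
            "wt1_stain_area": [p.wt1_stain_area for p in rows],
        }
    )


def profile_summary(
    profiles: Iterable[GlomerularProfile] | pd.DataFrame,
) -> ProfileSummary:
    """Per-profile means and the two areal ratios N_A and A_A.

    Ratios are computed as ratio-of-means (equivalently ratio of totals),
    which is unbiased under unequal profile areas:

    * ``N_A = mean(n_wt1) / mean(tuft_area)`` — nuclear profiles per μm²,
    * ``A_A = mean(wt1_stain_area) / mean(tuft_area)`` — stained areal
      fraction, a dimensionless number in [0, 1],
    * ``mean_nuclear_size = total stain area / total nuclei`` (NaN when no
      nucleus was counted).
    """
    df = _as_frame(profiles)
    if len(df) == 0:
        raise ValueError("need at least one profile")
    if (df["tuft_area"] <= 0).any():
        raise ValueError("all tuft areas must be positive")
    mean_tuft = float(df["tuft_area"].mean())
    total_n = float(df["n_wt1"].sum())
    n_a = total_n / float(df["tuft_area"].sum())
    a_a = float(df["wt1_stain_area"].sum()) / float(df["tuft_area"].sum())
    mean_size = float(df["wt1_stain_area"].sum()) / total_n if total_n > 0 else math.nan
    return ProfileSummary(n_a, a_a, mean_tuft, mean_size, len(df))


def nv_weibel_gomez(
    n_a: float,
    a_a: float,
    coeffs: StereologyCoefficients = DEFAULT_COEFFICIENTS,
) -> float:
    """Numerical density N_V = (K/β) · sqrt(N_A³ / A_A), nuclei per μm³.

    ``n_a = 0`` returns 0 regardless of ``a_a`` (an empty glomerulus has
    density zero); a positive count with a non-positive areal fraction is a
    contradiction and raises.
    """
    if n_a < 0:
        raise ValueError("N_A must be non-negative")
    if n_a == 0:
        return 0.0
    if a_a <= 0:
        raise ValueError("A_A must be positive when N_A > 0")
    return (coeffs.k_nuc / coeffs.beta_nuc) * math.sqrt(n_a**3 / a_a)


def vglom_weibel_gomez(
    mean_tuft_area: float,
    coeffs: StereologyCoefficients = DEFAULT_COEFFICIENTS,
) -> float:
    """Glomerular volume V = mean_tuft_area^1.5 · β/K, in μm³."""
    if mean_tuft_area < 0:
        raise ValueError("mean tuft area must be non-negative")
    return mean_tuft_area**1.5 * coeffs.beta_glom / coeffs.k_glom


def npod_glom(n_v: float, v_glom: float) -> tuple[float, float]:
    """Podocytes per glomerulus ``N_pod = N_V · V_glom``.

    Returns ``(n_pod, density)`` where density is podocytes per 10⁶ μm³.
    """
    if n_v < 0 or v_glom < 0:
        raise ValueError("N_V and V_glom must be non-negative")
    return n_v * v_glom, n_v * 1e6


def estimate_podocytes(
    profiles: Iterable[GlomerularProfile] | pd.DataFrame,
    coeffs: StereologyCoefficients = DEFAULT_COEFFICIENTS,
) -> PodocyteEstimate:
    """Compose the full chain: profiles → N_A, A_A → N_V, V_glom → N_pod."""
    summ = profile_summary(profiles)
    n_v = nv_weibel_gomez(summ.n_a, summ.a_a, coeffs) if summ.n_a > 0 else 0.0
    v_glom = vglom_weibel_gomez(summ.mean_tuft_area, coeffs)
    n_pod, density = npod_glom(n_v, v_glom)
    return PodocyteEstimate(
        n_a=summ.n_a,
        a_a=summ.a_a,
        n_v=n_v,
        v_glom=v_glom,
        n_pod=n_pod,
        density=density,
        mean_nuclear_size=summ.mean_nuclear_size,
        n_profiles=summ.n_profiles,
    )


def estimate_by_animal(
    profiles: pd.DataFrame,
    coeffs: StereologyCoefficients = DEFAULT_COEFFICIENTS,
    group_cols: tuple[str, ...] = ("group", "age_week"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-animal estimates from pooled profiles, then cohort means.

    ``profiles`` must carry an ``animal_id`` column plus the profile columns;
    cohort values are unweighted means of the per-animal estimates, matching
    the convention of averaging per-animal stereological readouts.
    """
    if "animal_id" not in profiles.columns:
        raise ValueError("profiles table must carry an animal_id column")
    records = []
    for animal, sub in profiles.groupby("animal_id", sort=True):
        est = estimate_podocytes(sub, coeffs)
        rec = {"animal_id": animal}
        for col in group_cols:
            if col in sub.columns:
                rec[col] = sub[col].iloc[0]
        rec.update(
            n_a=est.n_a,
            a_a=est.a_a,
            n_v=est.n_v,
            v_glom_um3=est.v_glom,
            n_pod=est.n_pod,
            density_per_1e6um3=est.density,
            mean_nuclear_size_um2=est.mean_nuclear_size,
            n_profiles=est.n_profiles,
        )
        records.append(rec)
    per_animal = pd.DataFrame(records)
    keys = [c for c in group_cols if c in per_animal.columns]
    if keys:
        per_cohort = (
            per_animal.groupby(keys, sort=True)
            .agg(
                n_animals=("animal_id", "size"),
                n_pod=("n_pod", "mean"),
                v_glom_um3=("v_glom_um3", "mean"),
                density_per_1e6um3=("density_per_1e6um3", "mean"),
                mean_nuclear_size_um2=("mean_nuclear_size_um2", "mean"),
            )
            .reset_index()
        )
    else:
        per_cohort = per_animal.copy()
    return per_animal, per_cohort
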