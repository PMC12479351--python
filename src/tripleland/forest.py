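"""Forest growth, sequestration and harvest model.

Stand growth is summarised by a yield class (YC, the maximum mean annual
volume increment in m^3/ha/yr) and a logistic cumulative-sequestration curve,
standing in for yield-class lookup tables. All quantities are expressed per
hectare and converted to CO2-equivalent mass with a fixed volume-to-CO2
factor (0.4 t biomass/m^3 x 0.5 t C/t biomass x 44/12 = 0.733 t CO2/m^3).

Plantations (coniferous, managed) are thinned — a fixed fraction of the
cumulative increment is removed and sold along the way — and clearfelled at
the age of maximum mean annual increment, then replanted. Broadleaved
woodland is unmanaged: no thinning, no felling, no timber revenue.

Benefit maps need the *mean annual* sequestration and harvest over the
accounting horizon (default 30 years, 2020-2050), for three stand states:
an existing plantation of a given mean age, existing broadleaved woodland,
and new woodland assumed planted uniformly over the horizon.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: t CO2 per m^3 of stem volume (density 0.4 t/m^3, carbon fraction 0.5).
VOLUME_TO_CO2 = 0.4 * 0.5 * 44.0 / 12.0


@dataclass
class ForestModel:
    """Logistic stand-growth model parameterised by yield class.

    ``horizon`` is the accounting window in years. ``thinning_fraction`` is
    the share of cumulative increment removed by thinning in managed stands.
    ``existing_plantation_age`` / ``existing_broadleaf_age`` are the assumed
    mean ages of already-established stands at the start of the horizon.
    """

    horizon: float = 30.0
    thinning_fraction: float = 0.3
    existing_plantation_age: float = 25.0
    existing_broadleaf_age: float = 60.0
    volume_to_co2: float = VOLUME_TO_CO2

    def felling_age(self, yield_class):
        """Age of maximum mean annual increment; higher YC stands are felled
        younger (YC 24 ~ 42 yr, YC 6 ~ 85 yr)."""
        return np.clip(100.0 - 2.4 * np.asarray(yield_class, dtype=float), 40.0, 85.0)

    def cumulative_co2(self, yield_class, age):
        """Cumulative sequestration (t CO2/ha) of a stand at ``age`` years.

        Logistic in age, anchored so that the mean annual increment at the
        felling age equals the yield class.
        """
        yc = np.asarray(yield_class, dtype=float)
        age = np.asarray(age, dtype=float)
        a_f = self.felling_age(yc)
        t_m = 0.6 * a_f
        r = 5.0 / a_f
        raw = lambda t: 1.0 / (1.0 + np.exp(-r * (t - t_m)))  # noqa: E731
        # shift so the curve starts at zero, scale so Q(a_f) = yc * a_f * v2c
        target = yc * a_f * self.volume_to_co2
        q = (raw(np.maximum(age, 0.0)) - raw(0.0)) / (raw(a_f) - raw(0.0))
        return target * q

    # -- mean annual rates over the horizon -------------------------------

    def _new_planting_mean_cumulative(self, yield_class):
        """Mean cumulative sequestration at horizon end across a cohort
        planted uniformly over the horizon (numerical average of Q over
        ages 0..horizon)."""
        ages = np.linspace(0.0, self.horizon, 61)
        q = self.cumulative_co2(np.asarray(yield_class, dtype=float)[..., None], ages)
        return np.trapezoid(q, ages, axis=-1) / self.horizon

    def mean_annual_sequestration(self, yield_class, *, managed: bool,
                                  new_planting) -> np.ndarray:
        """Mean annual gross sequestration over the horizon, t CO2/ha/yr.

        ``new_planting`` is a boolean array (or scalar) marking cells where
        the stand does not yet exist. Managed stands are felled at the age
        of maximum MAI and replanted; harvested biomass counts as
        sequestered here (its long-term fate is handled by the wood-product
        share downstream).
        """
        yc = np.asarray(yield_class, dtype=float)
        new_planting = np.broadcast_to(np.asarray(new_planting, dtype=bool), yc.shape)
        H = self.horizon
        a0 = self.existing_plantation_age if managed else self.existing_broadleaf_age

        inc_new = self._new_planting_mean_cumulative(yc)

        a_f = self.felling_age(yc)
        if managed:
            fell = a0 + H >= a_f
            inc_exist = np.where(
                fell,
                self.cumulative_co2(yc, a_f)
                - self.cumulative_co2(yc, np.minimum(a0, a_f))
                + self.cumulative_co2(yc, np.maximum(a0 + H - a_f, 0.0)),
                self.cumulative_co2(yc, a0 + H) - self.cumulative_co2(yc, a0),
            )
        else:
            inc_exist = self.cumulative_co2(yc, a0 + H) - self.cumulative_co2(yc, a0)

        return np.where(new_planting, inc_new, inc_exist) / H

    def mean_annual_harvest(self, yield_class, *, new_planting) -> np.ndarray:
        """Mean annual harvested biomass over the horizon in t CO2/ha/yr
        (managed plantations only: thinnings plus clearfell where the
        felling age falls inside the horizon)."""
        yc = np.asarray(yield_class, dtype=float)
        new_planting = np.broadcast_to(np.asarray(new_planting, dtype=bool), yc.shape)
        H = self.horizon
        th = self.thinning_fraction
        a_f = self.felling_age(yc)
        a0 = self.existing_plantation_age

        # existing stands: thin until felling, clearfell standing stock,
        # thin the regrowth
        fell = a0 + H >= a_f
        q0 = self.cumulative_co2(yc, a0)
        harv_exist = np.where(
            fell,
            th * (self.cumulative_co2(yc, a_f) - q0)
            + (1.0 - th) * self.cumulative_co2(yc, a_f)
            + th * self.cumulative_co2(yc, np.maximum(a0 + H - a_f, 0.0)),
            th * (self.cumulative_co2(yc, a0 + H) - q0),
        )

        # new cohort, planted uniformly: mostly thinnings; clearfell only for
        # the (usually empty) share of the cohort reaching felling age
        harv_new = th * self._new_planting_mean_cumulative(yc)
        frac_felled = np.clip((H - a_f) / H, 0.0, 1.0)
        harv_new = harv_new + frac_felled * (1.0 - th) * self.cumulative_co2(yc, a_f)

        return np.where(new_planting, harv_new, harv_exist) / H
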