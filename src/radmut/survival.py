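"""Single-hit multitarget survival model for acute-irradiation assays.

The model assumes each organism carries ``n`` radiosensitive targets,
each inactivated independently with mean lethal dose ``D0``; death
requires all targets hit, giving the surviving fraction

    S(D) = 1 - (1 - exp(-D / D0))**n,        D0 > 0, n >= 1.

``n`` (the extrapolation number) controls the low-dose shoulder whose
width is the quasi-threshold dose Dq = D0 * ln(n); n = 1 is the pure
exponential (shoulderless) curve with Dq = 0.

The API follows the fitted-model convention: build a
:class:`SingleHitMultiTargetModel` from dose/fraction data (or from raw
sown/survived observations), call :meth:`fit`, and read estimates,
standard errors and diagnostics off the returned
:class:`SurvivalFitResults`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares


@dataclass(frozen=True)
class SurvivalObservation:
    dose_gy: float
    n_sown: int
    n_survived: int
    replicate: str = "1"

    def __post_init__(self) -> None:
        if self.n_sown <= 0:
            raise ValueError("n_sown must be positive")
        if not 0 <= self.n_survived <= self.n_sown:
            raise ValueError("n_survived outside [0, n_sown]")
        if self.dose_gy < 0:
            raise ValueError("dose_gy must be >= 0")

    @property
    def fraction(self) -> float:
        return self.n_survived / self.n_sown


def multitarget_survival(dose, d0: float, n: float):
    """S(D) = 1 - (1 - exp(-D/D0))^n; equals 1 at D = 0 for any params."""
    dose = np.asarray(dose, dtype=float)
    return 1.0 - (1.0 - np.exp(-dose / d0)) ** n


def survival_fractions(
    observations: list[SurvivalObservation], normalize: bool = False
) -> pd.DataFrame:
    """Per-dose mean survival fraction with SE across replicates.

    With ``normalize=True`` the means are divided by the 0-Gy control
    mean when that control is below 1.
    """
    if not observations:
        raise ValueError("no observations")
    df = pd.DataFrame(
        {
            "dose_gy": [o.dose_gy for o in observations],
            "fraction": [o.fraction for o in observations],
        }
    )
    grouped = df.groupby("dose_gy")["fraction"]
    out = pd.DataFrame(
        {
            "mean": grouped.mean(),
            "se": grouped.sem(ddof=1),
            "n_replicates": grouped.size(),
        }
    ).reset_index()
    out.loc[out["n_replicates"] == 1, "se"] = np.nan
    if normalize and 0.0 in set(out["dose_gy"]):
        control = float(out.loc[out["dose_gy"] == 0.0, "mean"].iloc[0])
        if 0 < control < 1:
            out["mean"] = out["mean"] / control
            out["se"] = out["se"] / control
    return out


# default multi-start grid; log-spaced to cover shoulder widths from
# tens to thousands of gray
_D0_GRID = tuple(np.geomspace(10.0, 5000.0, 10))
_N_GRID = (1.0, 1.5, 2.0, 3.0, 5.0, 8.0, 15.0, 40.0)


class SingleHitMultiTargetModel:
    """Least-squares fit of the multitarget curve to survival fractions.

    Parameters
    ----------
    doses, fractions
        Dose points (Gy) and observed surviving fractions in (0, 1].
        At least 3 distinct doses are required, one of them low-dose
        (below the eventual shoulder) or a 0-Gy control.
    """

    def __init__(self, doses, fractions):
        self.doses = np.asarray(doses, dtype=float)
        self.fractions = np.asarray(fractions, dtype=float)
        if self.doses.shape != self.fractions.shape:
            raise ValueError("doses and fractions differ in length")
        if len(np.unique(self.doses)) < 3:
            raise ValueError("need at least 3 distinct doses")
        if np.any(self.fractions <= 0) or np.any(self.fractions > 1):
            raise ValueError("fractions must lie in (0, 1]; floor zeros first")

    @classmethod
    def from_observations(
        cls,
        observations: list[SurvivalObservation],
        normalize: bool = False,
        zero_floor: float | None = None,
    ) -> "SingleHitMultiTargetModel":
        """Build from raw sown/survived counts, averaging replicates.

        Zero survival at a dose is replaced by ``zero_floor`` (default
        1 / (2 * total plants sown at that dose)) so the fraction stays
        in the model's open interval.
        """
        table = survival_fractions(observations, normalize=normalize)
        sown = pd.DataFrame(
            {
                "dose_gy": [o.dose_gy for o in observations],
                "n_sown": [o.n_sown for o in observations],
            }
        ).groupby("dose_gy")["n_sown"].sum()
        fracs = []
        for _, row in table.iterrows():
            f = row["mean"]
            if f <= 0:
                f = (
                    zero_floor
                    if zero_floor is not None
                    else 1.0 / (2.0 * sown[row["dose_gy"]])
                )
            fracs.append(min(f, 1.0))
        return cls(table["dose_gy"].to_numpy(), np.asarray(fracs))

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, dose_col: str = "dose_gy", frac_col: str = "fraction"
    ) -> "SingleHitMultiTargetModel":
        return cls(df[dose_col].to_numpy(), df[frac_col].to_numpy())

    def _residuals(self, params):
        d0, n = params
        return multitarget_survival(self.doses, d0, n) - self.fractions

    def fit(self, d0_grid=_D0_GRID, n_grid=_N_GRID) -> "SurvivalFitResults":
        """Multi-start bounded least squares on the linear fraction scale.

        Starts span a log-spaced (D0, n) grid; the surface is non-convex
        in n, so the best local optimum is chosen by lowest residual sum
        of squares, ties broken toward lower n.
        """
        best = None
        diagnostics = []
        for d0_start in d0_grid:
            for n_start in n_grid:
                try:
                    res = least_squares(
                        self._residuals,
                        x0=[d0_start, n_start],
                        bounds=([1e-9, 1.0], [np.inf, np.inf]),
                        xtol=1e-14,
                        ftol=1e-14,
                        gtol=1e-14,
                    )
                except Exception as exc:  # pragma: no cover - defensive
                    diagnostics.append(f"start ({d0_start:.3g}, {n_start:.3g}): {exc}")
                    continue
                if not res.success:
                    diagnostics.append(
                        f"start ({d0_start:.3g}, {n_start:.3g}): {res.message}"
                    )
                    continue
                rss = float(2 * res.cost)
                key = (round(rss, 12), res.x[1])
                if best is None or key < best[0]:
                    best = (key, res)
        if best is None:
            raise RuntimeError(
                "single-hit multitarget fit failed on every start: "
                + "; ".join(diagnostics[:5])
            )
        res = best[1]
        return SurvivalFitResults(self, res)


class SurvivalFitResults:
    """Estimates, uncertainties and diagnostics of a multitarget fit."""

    def __init__(self, model: SingleHitMultiTargetModel, optres):
        self.model = model
        self.d0_gy, self.n_extrapolation = (float(v) for v in optres.x)
        resid = optres.fun
        self.rss = float(np.sum(resid**2))
        self.nobs = len(model.doses)
        self._compute_bse(optres.jac)

    def _compute_bse(self, jac) -> None:
        dof = max(self.nobs - 2, 1)
        s2 = self.rss / dof
        jtj = jac.T @ jac
        try:
            cov = np.linalg.inv(jtj) * s2
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(jtj) * s2
        self.cov_params = cov
        self.bse = {
            "d0_gy": float(math.sqrt(max(cov[0, 0], 0.0))),
            "n_extrapolation": float(math.sqrt(max(cov[1, 1], 0.0))),
        }
        # delta method for Dq = D0 * ln(n): grad = (ln n, D0 / n)
        g = np.array([math.log(self.n_extrapolation), self.d0_gy / self.n_extrapolation])
        self.bse["dq_gy"] = float(math.sqrt(max(g @ cov @ g, 0.0)))

    @property
    def dq_gy(self) -> float:
        """Quasi-threshold (shoulder) dose Dq = D0 * ln(n)."""
        return self.d0_gy * math.log(self.n_extrapolation)

    @property
    def params(self) -> dict[str, float]:
        return {
            "d0_gy": self.d0_gy,
            "n_extrapolation": self.n_extrapolation,
            "dq_gy": self.dq_gy,
        }

    def predict(self, doses) -> np.ndarray:
        return multitarget_survival(doses, self.d0_gy, self.n_extrapolation)

    def curve_table(self, doses=None) -> pd.DataFrame:
        """Predicted-survival table for plotting."""
        if doses is None:
            doses = np.linspace(0.0, float(self.model.doses.max()) * 1.1, 101)
        return pd.DataFrame(
            {"dose_gy": np.asarray(doses, float), "survival": self.predict(doses)}
        )

    def summary(self) -> str:
        lines = [
            "Single-hit multitarget survival fit",
            "=" * 42,
            f"{'n observations':<24}{self.nobs:>18d}",
            f"{'residual sum of squares':<24}{self.rss:>18.6g}",
            "-" * 42,
            f"{'parameter':<16}{'estimate':>12}{'std err':>12}",
            f"{'D0 (Gy)':<16}{self.d0_gy:>12.4g}{self.bse['d0_gy']:>12.3g}",
            (
                f"{'n (targets)':<16}{self.n_extrapolation:>12.4g}"
                f"{self.bse['n_extrapolation']:>12.3g}"
            ),
            f"{'Dq (Gy)':<16}{self.dq_gy:>12.4g}{self.bse['dq_gy']:>12.3g}",
            "=" * 42,
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<SurvivalFitResults D0={self.d0_gy:.4g} Gy, "
            f"n={self.n_extrapolation:.4g}, Dq={self.dq_gy:.4g} Gy>"
        )


def fit_single_hit_multitarget(doses, fractions) -> SurvivalFitResults:
    """Convenience wrapper: build the model and fit with default starts."""
    return SingleHitMultiTargetModel(doses, fractions).fit()
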