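"""Tuning-curve basis expansions for each recording modality.

Each brain area gets the canonical tuning model of its literature:

- ``cosine_direction`` — motor/visual cortex: f(theta) = [cos theta, sin theta],
  the classic cosine-tuning parameterisation (K = 2).
- ``cosine_direction_plus_speed`` — somatosensory cortex: the two direction
  cosines plus a linear hand-speed column in cm/s (K = 3).
- ``rbf_grid_2d`` — hippocampal place fields: K = 25 isotropic Gaussian
  radial basis functions on a 5x5 grid over the arena, sigma = 9 cm.
- ``rbf_logfreq`` — auditory cortex tonotopy: K = 7 Gaussians equally
  spaced in log-frequency over 6.4 octaves (0.18-15.56 kHz),
  sigma = 0.64 octaves.

RBFs are unnormalised Gaussians with peak value 1 at their centre, so the
tuning weights stay on the log-rate scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import CovariateTable

__all__ = ["BasisSpec", "build_basis", "basis_grid"]

BASIS_KINDS = (
    "cosine_direction",
    "cosine_direction_plus_speed",
    "rbf_grid_2d",
    "rbf_logfreq",
)

# A1 tone set spans 6.4 octaves; on our octave axis that is [0, 6.4].
_LOGFREQ_SPAN = (0.0, 6.4)


@dataclass
class BasisSpec:
    """Specification of a tuning basis.

    Parameters
    ----------
    kind : str
        One of ``cosine_direction``, ``cosine_direction_plus_speed``,
        ``rbf_grid_2d``, ``rbf_logfreq``.
    K : int, optional
        Number of basis functions.  Fixed at 2 (or 3 with speed) for the
        cosine bases; defaults to 25 for the 2-D grid and 7 for the
        log-frequency axis.
    centers : ndarray, optional
        RBF centres — (K, 2) grid positions in cm, or (K,) log-frequencies
        in octaves.  Defaults to an equally spaced tiling.
    width : float, optional
        RBF standard deviation (9 cm for the place grid, 0.64 octaves for
        the tonotopic axis).
    extent : tuple, optional
        For ``rbf_grid_2d``: (xmin, xmax, ymin, ymax) of the arena in cm.
    """

    kind: str
    K: int | None = None
    centers: np.ndarray | None = None
    width: float | None = None
    extent: tuple[float, float, float, float] = (0.0, 180.0, 0.0, 180.0)
    logfreq_span: tuple[float, float] = _LOGFREQ_SPAN
    required: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        if self.kind not in BASIS_KINDS:
            raise ValueError(f"unknown basis kind {self.kind!r}")
        if self.kind == "cosine_direction":
            self.K = 2
            self.required = ("direction",)
        elif self.kind == "cosine_direction_plus_speed":
            self.K = 3
            self.required = ("direction", "speed")
        elif self.kind == "rbf_grid_2d":
            self.required = ("pos_x", "pos_y")
            if self.width is None:
                self.width = 9.0
            if self.centers is None:
                side = 5 if self.K is None else int(round(np.sqrt(self.K)))
                if side * side != (self.K or side * side):
                    raise ValueError("rbf_grid_2d needs a square K")
                x0, x1, y0, y1 = self.extent
                cx = np.linspace(x0, x1, side)
                cy = np.linspace(y0, y1, side)
                gx, gy = np.meshgrid(cx, cy, indexing="xy")
                self.centers = np.column_stack([gx.ravel(), gy.ravel()])
            self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
            self.K = self.centers.shape[0]
        elif self.kind == "rbf_logfreq":
            self.required = ("log_frequency",)
            if self.width is None:
                self.width = 0.64
            if self.K is None:
                self.K = 7
            if self.centers is None:
                lo, hi = self.logfreq_span
                self.centers = np.linspace(lo, hi, self.K)
            self.centers = np.asarray(self.centers, dtype=float).ravel()
            self.K = self.centers.shape[0]


def build_basis(covariates: CovariateTable, spec: BasisSpec) -> np.ndarray:
    """Evaluate the tuning basis on every trial.

    Returns a (n_trials, K) real matrix — the tuning block of the design
    matrix.  Raises KeyError naming the first missing covariate.
    """
    for col in spec.required:
        if not covariates.has(col):
            raise KeyError(
                f"basis kind {spec.kind!r} needs covariate {col!r}, "
                "which is not present"
            )
    if spec.kind in ("cosine_direction", "cosine_direction_plus_speed"):
        theta = np.deg2rad(covariates["direction"])
        cols = [np.cos(theta), np.sin(theta)]
        if spec.kind == "cosine_direction_plus_speed":
            cols.append(np.asarray(covariates["speed"], dtype=float))
        out = np.column_stack(cols)
    elif spec.kind == "rbf_grid_2d":
        pos = np.column_stack([covariates["pos_x"], covariates["pos_y"]])
        d2 = ((pos[:, None, :] - spec.centers[None, :, :]) ** 2).sum(axis=2)
        out = np.exp(-0.5 * d2 / spec.width**2)
    else:  # rbf_logfreq
        lf = np.asarray(covariates["log_frequency"], dtype=float)
        out = np.exp(-0.5 * (lf[:, None] - spec.centers[None, :]) ** 2 / spec.width**2)
    if not np.all(np.isfinite(out)):
        raise ValueError("non-finite values in tuning basis")
    return out


def basis_grid(spec: BasisSpec, n: int = 512) -> CovariateTable:
    """A dense grid over the stimulus domain, for modulation/preference.

    For direction bases the grid covers [0, 360) degrees (speed fixed at
    its basis-free value 0 is not meaningful, so a unit speed is used);
    for RBF bases it spans the centre range per dimension.
    """
    import pandas as pd

    if spec.kind in ("cosine_direction", "cosine_direction_plus_speed"):
        df = pd.DataFrame({"direction": np.linspace(0.0, 360.0, n, endpoint=False)})
        if spec.kind == "cosine_direction_plus_speed":
            df["speed"] = 1.0
    elif spec.kind == "rbf_grid_2d":
        m = int(np.sqrt(n))
        xs = np.linspace(spec.centers[:, 0].min(), spec.centers[:, 0].max(), m)
        ys = np.linspace(spec.centers[:, 1].min(), spec.centers[:, 1].max(), m)
        gx, gy = np.meshgrid(xs, ys, indexing="xy")
        df = pd.DataFrame({"pos_x": gx.ravel(), "pos_y": gy.ravel()})
    else:
        df = pd.DataFrame(
            {"log_frequency": np.linspace(spec.centers.min(), spec.centers.max(), n)}
        )
    return CovariateTable(df)
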