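"""Synthetic ground-truth systems and umbrella campaigns.

This module stands in for the MD engine: it generates umbrella-window data
with the statistical structure the analysis assumes — overdamped Langevin
dynamics on a periodic model free-energy landscape with (optionally)
position-dependent diffusivity, harmonic window biases, and neighbor
configuration exchanges — plus a brute-force first-passage oracle against
which the Smoluchowski double-integral passage times can be validated.

Landscapes are truncated Fourier series on a 360 degree period.  The
flipping-like preset places an intra-helical minimum near +30 deg, an
extra-helical minimum near -135 deg, and a tunable barrier between them, the
geometry of the base-flipping free-energy profiles the analysis targets.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.integrate import quad

from flipkin import _kernels
from flipkin.angles import wrap_angle
from flipkin.constants import DEG2RAD, RAD2DEG, kt_kcal
from flipkin.umbrella import AngleSeries, UmbrellaWindow, WindowSet
from flipkin.wham import Extremum, FreeEnergyProfile

_TABLE_N = 4096


def _fourier_eval(a: np.ndarray, b: np.ndarray, x: np.ndarray) -> np.ndarray:
    """sum_n a_n cos(n x) + b_n sin(n x) (x in radians)."""
    n = np.arange(len(a))
    return (a[None, :] * np.cos(np.outer(x, n))
            + b[None, :] * np.sin(np.outer(x, n))).sum(axis=1)


def _fourier_deriv(a: np.ndarray, b: np.ndarray, x: np.ndarray) -> np.ndarray:
    n = np.arange(len(a))
    return (-a[None, :] * n * np.sin(np.outer(x, n))
            + b[None, :] * n * np.cos(np.outer(x, n))).sum(axis=1)


def _fourier_fit(values: np.ndarray, n_modes: int) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares Fourier truncation of samples on a uniform [0, 2pi) grid."""
    coeff = np.fft.rfft(values) / values.size
    a = np.zeros(n_modes + 1)
    b = np.zeros(n_modes + 1)
    a[0] = coeff[0].real
    a[1:] = 2.0 * coeff[1:n_modes + 1].real
    b[1:] = -2.0 * coeff[1:n_modes + 1].imag
    return a, b


@dataclass
class HarmonicBias:
    """Umbrella bias: 1/2 k d(xi - center)^2, periodic distance in radians."""

    center: float           # deg
    force_constant: float   # kcal mol^-1 rad^-2


@dataclass
class SimulationSpec:
    """Langevin integration settings.

    The default timestep resolves the stiffest mode of the study conditions
    (windows at 400 kcal mol^-1 rad^-2 with D ~ 0.15 rad^2/ps relax in
    ~0.01 ps); a drift-stability check rejects settings whose per-step drift
    could exceed 0.2 rad.
    """

    dt: float = 2.5e-4              # ps
    n_samples: int = 100_000        # stored samples
    stride: int = 5                 # steps between stored samples
    equilibration_steps: int = 10_000
    seed: int = 0
    initial: float | None = None    # deg; default: bias center or 0
    bias: HarmonicBias | None = None

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_samples < 2 or self.stride < 1 or self.equilibration_steps < 0:
            raise ValueError("invalid sampling sizes")


class StabilityError(ValueError):
    """Timestep too large for the requested landscape/bias."""


@dataclass
class ModelSystem:
    """Ground-truth system: Fourier free energy, diffusivity, temperature.

    ``f_cos``/``f_sin`` are Fourier coefficients of F(xi) in kcal/mol
    (index = harmonic order, xi in radians); ``d_log_cos``/``d_log_sin``
    those of ln D (D in rad^2/ps), so D is strictly positive by construction.
    """

    f_cos: np.ndarray
    f_sin: np.ndarray
    d_log_cos: np.ndarray
    d_log_sin: np.ndarray
    temperature: float = 300.0
    label: str = "model"

    def __post_init__(self) -> None:
        self.f_cos = np.atleast_1d(np.asarray(self.f_cos, dtype=float))
        self.f_sin = np.atleast_1d(np.asarray(self.f_sin, dtype=float))
        self.d_log_cos = np.atleast_1d(np.asarray(self.d_log_cos, dtype=float))
        self.d_log_sin = np.atleast_1d(np.asarray(self.d_log_sin, dtype=float))
        if self.f_cos.shape != self.f_sin.shape:
            raise ValueError("f_cos and f_sin must have equal length")
        if self.d_log_cos.shape != self.d_log_sin.shape:
            raise ValueError("d_log_cos and d_log_sin must have equal length")

    # -- landscape evaluation -------------------------------------------------

    def free_energy(self, xi_deg) -> np.ndarray:
        """F (kcal/mol) at angles in degrees (any branch)."""
        x = np.atleast_1d(np.asarray(xi_deg, dtype=float)) * DEG2RAD
        out = _fourier_eval(self.f_cos, self.f_sin, x)
        return float(out[0]) if np.ndim(xi_deg) == 0 else out

    def diffusivity(self, xi_deg) -> np.ndarray:
        """D (rad^2/ps) at angles in degrees."""
        x = np.atleast_1d(np.asarray(xi_deg, dtype=float)) * DEG2RAD
        out = np.exp(_fourier_eval(self.d_log_cos, self.d_log_sin, x))
        return float(out[0]) if np.ndim(xi_deg) == 0 else out

    def tables(self, n: int = _TABLE_N):
        """(F', D, D') lookup tables on [0, 2pi) for the Langevin kernels."""
        x = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
        fprime = _fourier_deriv(self.f_cos, self.f_sin, x)
        lnd = _fourier_eval(self.d_log_cos, self.d_log_sin, x)
        dlnd = _fourier_deriv(self.d_log_cos, self.d_log_sin, x)
        d = np.exp(lnd)
        return fprime, d, d * dlnd

    def true_profile(self, bin_centers_deg: np.ndarray) -> FreeEnergyProfile:
        """Ground-truth F on a grid, min-referenced, fully 'occupied'."""
        vals = self.free_energy(bin_centers_deg)
        vals = vals - vals.min()
        return FreeEnergyProfile(
            bin_centers=np.asarray(bin_centers_deg, float), values=vals,
            occupancy=np.ones(len(vals)), temperature=self.temperature,
        )

    def extrema(self, branch: tuple[float, float] = (-321.0, 39.0)
                ) -> list[Extremum]:
        """Local extrema (deg, kcal/mol, min-referenced F) on a branch."""
        grid = np.linspace(branch[0], branch[1], 1 << 15)
        f = self.free_energy(grid)
        f = f - f.min()
        out = []
        for i in range(1, len(grid) - 1):
            if f[i] < f[i - 1] and f[i] < f[i + 1]:
                kind = "min"
            elif f[i] > f[i - 1] and f[i] > f[i + 1]:
                kind = "max"
            else:
                continue
            # parabolic refinement
            denom = f[i - 1] - 2 * f[i] + f[i + 1]
            shift = 0.5 * (f[i - 1] - f[i + 1]) / denom if denom != 0 else 0.0
            pos = grid[i] + shift * (grid[1] - grid[0])
            val = float(self.free_energy(pos) - (self.free_energy(grid).min()))
            out.append(Extremum(float(pos), val, kind))
        return out

    @property
    def beta(self) -> float:
        return 1.0 / kt_kcal(self.temperature)

    # -- serialization --------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "f_cos": self.f_cos.tolist(), "f_sin": self.f_sin.tolist(),
            "d_log_cos": self.d_log_cos.tolist(),
            "d_log_sin": self.d_log_sin.tolist(),
            "temperature": self.temperature, "label": self.label,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSystem":
        return cls(
            f_cos=np.array(d["f_cos"]), f_sin=np.array(d["f_sin"]),
            d_log_cos=np.array(d["d_log_cos"]),
            d_log_sin=np.array(d["d_log_sin"]),
            temperature=d["temperature"], label=d.get("label", "model"),
        )

    # -- presets --------------------------------------------------------------

    @classmethod
    def flat(cls, diffusivity: float = 0.15, temperature: float = 300.0
             ) -> "ModelSystem":
        """Flat landscape, constant diffusivity (rad^2/ps)."""
        return cls(
            f_cos=[0.0], f_sin=[0.0],
            d_log_cos=[float(np.log(diffusivity))], d_log_sin=[0.0],
            temperature=temperature, label="flat",
        )

    @classmethod
    def single_well(cls, position: float = 0.0, depth: float = 2.0,
                    diffusivity: float = 0.15, temperature: float = 300.0
                    ) -> "ModelSystem":
        """F = depth/2 * (1 - cos(xi - position)): one minimum, one barrier."""
        mu = position * DEG2RAD
        return cls(
            f_cos=[depth / 2, -depth / 2 * np.cos(mu)],
            f_sin=[0.0, -depth / 2 * np.sin(mu)],
            d_log_cos=[float(np.log(diffusivity))], d_log_sin=[0.0],
            temperature=temperature, label="single-well",
        )

    @classmethod
    def flipping_double_well(
        cls,
        intra: float = 30.0,
        extra: float = -135.0,
        barrier: float = 3.0,
        delta_f: float = -2.0,
        kappa: float = 2.0,
        n_modes: int = 10,
        diffusivity: float = 0.15,
        d_log_amplitude: float = 0.0,
        temperature: float = 300.0,
    ) -> "ModelSystem":
        """Base-flipping-like double well.

        Minima at ``intra`` and ``extra`` (deg), a barrier of ``barrier``
        kcal/mol above the intra-helical minimum on the direct path between
        the two states, and a state offset ``delta_f = F(extra) - F(intra)``
        (negative = extra-helical state more stable, as for the damaged base
        in the enzyme active site).  ``kappa`` sets the well widths.  The
        shape is a Fourier truncation of a two-component periodic
        (von-Mises-like) well mixture, calibrated so the realized minima land
        within 0.5 deg and barrier/offset within 0.05 kcal/mol of the
        requested values.  ``d_log_amplitude`` > 0 adds a log-sinusoidal
        diffusivity modulation (1.151 gives one order of magnitude
        peak-to-trough).
        """
        if not -12.0 <= delta_f <= 12.0 or not 0.5 <= barrier <= 12.0:
            raise ValueError("barrier/delta_f outside the supported range")
        a, b, scale = _calibrate_double_well(
            intra * DEG2RAD, extra * DEG2RAD, barrier, delta_f, kappa, n_modes
        )
        phase = 1.0  # rad; fixes where rough-D peaks sit relative to the wells
        d_log_cos = np.zeros(3)
        d_log_sin = np.zeros(3)
        d_log_cos[0] = np.log(diffusivity)
        if d_log_amplitude:
            d_log_cos[2] = d_log_amplitude * np.cos(2 * phase)
            d_log_sin[2] = d_log_amplitude * np.sin(2 * phase)
        model = cls(
            f_cos=a * scale, f_sin=b * scale,
            d_log_cos=d_log_cos, d_log_sin=d_log_sin,
            temperature=temperature, label="flipping-double-well",
        )
        _verify_preset(model, intra, extra, barrier, delta_f)
        return model


def _calibrate_double_well(mu1, mu2, barrier, delta_f, kappa, n_modes):
    """Fit mixture centers and weight so the truncated Fourier landscape has
    minima at mu1/mu2 and offset/barrier in the requested proportion; returns
    (a, b, scale)."""
    grid = np.linspace(0.0, 2 * np.pi, _TABLE_N, endpoint=False)
    c1, c2 = mu1, mu2
    lnw = 0.0
    rho_target = delta_f / barrier
    a = b = None
    for _ in range(200):
        g = -np.log(
            np.exp(kappa * np.cos(grid - c1))
            + np.exp(lnw + kappa * np.cos(grid - c2))
        )
        a, b = _fourier_fit(g, n_modes)
        p1, v1 = _refine_extremum(a, b, mu1, "min")
        p2, v2 = _refine_extremum(a, b, mu2, "min")
        ps, vs = _segment_saddle(a, b, mu1, mu2)
        barrier_g = vs - v1
        rho = (v2 - v1) / barrier_g
        err1 = wrap_angle((mu1 - p1) * RAD2DEG) * DEG2RAD
        err2 = wrap_angle((mu2 - p2) * RAD2DEG) * DEG2RAD
        c1 += err1
        c2 += err2
        lnw += 0.8 * (rho - rho_target) * barrier_g
        if abs(err1) < 1e-5 and abs(err2) < 1e-5 and abs(rho - rho_target) < 1e-5:
            break
    scale = barrier / barrier_g
    return a, b, scale


def _refine_extremum(a, b, near, kind, half_width=0.6, n=2001):
    x = np.linspace(near - half_width, near + half_width, n)
    f = _fourier_eval(a, b, x)
    i = int(np.argmin(f) if kind == "min" else np.argmax(f))
    return float(x[i]), float(f[i])


def _segment_saddle(a, b, mu1, mu2, n=4001):
    """Maximum on the direct branch segment between the two minima (the
    segment the passage-time analysis integrates over)."""
    x = np.linspace(mu2, mu1, n)
    f = _fourier_eval(a, b, x)
    i = int(np.argmax(f[1:-1])) + 1
    return float(x[i]), float(f[i])


def _verify_preset(model, intra, extra, barrier, delta_f):
    mins = [e for e in model.extrema() if e.kind == "min"]
    near_intra = min(mins, key=lambda e: abs(wrap_angle(e.position - intra)))
    near_extra = min(mins, key=lambda e: abs(wrap_angle(e.position - extra)))
    f_i = model.free_energy(near_intra.position)
    f_e = model.free_energy(near_extra.position)
    seg = np.linspace(extra, intra, 4001)
    bar = float(model.free_energy(seg).max() - f_i)
    ok = (
        abs(wrap_angle(near_intra.position - intra)) < 0.5
        and abs(wrap_angle(near_extra.position - extra)) < 0.5
        and abs(bar - barrier) < 0.05
        and abs((f_e - f_i) - delta_f) < 0.05
    )
    if not ok:
        raise RuntimeError(
            "double-well calibration failed: "
            f"minima at {near_intra.position:.2f}/{near_extra.position:.2f} deg, "
            f"barrier {bar:.3f}, offset {f_e - f_i:.3f} kcal/mol"
        )


# -- stability ---------------------------------------------------------------


def _validate_stability(model: ModelSystem, spec: SimulationSpec) -> None:
    fprime, d_tab, _ = model.tables()
    beta = model.beta
    d_max = float(d_tab.max())
    drift = beta * d_max * float(np.abs(fprime).max()) * spec.dt
    if spec.bias is not None:
        k = spec.bias.force_constant
        theta = beta * d_max * k * spec.dt
        if theta > 0.5:
            raise StabilityError(
                f"beta*D*k*dt = {theta:.2f} > 0.5: harmonic window unstable; "
                "reduce dt"
            )
        sigma = np.sqrt(1.0 / (beta * k))
        drift += beta * d_max * k * 5.0 * sigma * spec.dt
    if drift > 0.2:
        raise StabilityError(
            f"per-step drift bound {drift:.3f} rad > 0.2; reduce dt"
        )


def _sub_seeds(seed: int, n: int) -> np.ndarray:
    """Counter-based per-walker substreams below 2**31 (numba-seedable)."""
    return np.random.SeedSequence(seed).generate_state(n) % (2**31 - 1)


# -- operations ---------------------------------------------------------------


def langevin_trajectory(model: ModelSystem, spec: SimulationSpec) -> AngleSeries:
    """One overdamped Langevin trajectory (Euler-Maruyama, Ito convention with
    the spurious-drift term for position-dependent D); deterministic for a
    given seed.  Returns stored angles in degrees on the continuous
    (unwrapped) branch; sampling interval is ``dt * stride``."""
    _validate_stability(model, spec)
    fprime, d_tab, dprime = model.tables()
    if spec.bias is not None:
        center = spec.bias.center * DEG2RAD
        k = spec.bias.force_constant
        biased = True
    else:
        center, k, biased = 0.0, 0.0, False
    x0 = spec.initial if spec.initial is not None else (
        spec.bias.center if spec.bias else 0.0
    )
    out = _kernels.langevin_window(
        x0 * DEG2RAD, spec.equilibration_steps, spec.n_samples, spec.stride,
        spec.dt, model.beta, fprime, d_tab, dprime, k, center, biased,
        int(spec.seed) % (2**31 - 1),
    )
    return AngleSeries(
        dt=spec.dt * spec.stride, values=out * RAD2DEG,
        label=f"{model.label} langevin seed={spec.seed}",
    )


@dataclass
class CampaignResult:
    """A synthetic umbrella campaign and its exchange statistics."""

    windows: WindowSet
    acceptance_rate: float
    n_attempts: int


def run_umbrella_campaign(
    model: ModelSystem,
    window_centers: Sequence[float],
    force_constant: float = 400.0,
    spec: SimulationSpec | None = None,
    exchange_every: int = 2000,
    seed: int | None = None,
) -> CampaignResult:
    """Biased walkers in every window with periodic neighbor exchanges.

    One walker per window (started at its center); every ``exchange_every``
    integration steps, neighbor pairs of alternating parity attempt a
    configuration swap accepted with the Metropolis probability on the bias
    energies — the replica-exchange umbrella-sampling move, which leaves each
    window's stationary distribution unchanged while decorrelating the
    ladder.  ``exchange_every=0`` disables exchanges.  Deterministic for a
    given seed.
    """
    spec = spec or SimulationSpec()
    if seed is None:
        seed = spec.seed
    centers = np.asarray(window_centers, dtype=float)
    if np.any(np.diff(centers) <= 0):
        raise ValueError("window centers must be sorted increasing")
    bias = HarmonicBias(center=float(centers[0]), force_constant=force_constant)
    _validate_stability(
        model, SimulationSpec(
            dt=spec.dt, n_samples=spec.n_samples, stride=spec.stride,
            equilibration_steps=spec.equilibration_steps, bias=bias,
        ),
    )
    fprime, d_tab, dprime = model.tables()
    stored, attempts, accepts = _kernels.campaign(
        centers * DEG2RAD, spec.equilibration_steps, spec.n_samples,
        spec.stride, int(exchange_every), spec.dt, model.beta,
        fprime, d_tab, dprime, force_constant, int(seed) % (2**31 - 1),
    )
    dt_store = spec.dt * spec.stride
    windows = []
    for i, c in enumerate(centers):
        deg = stored[i] * RAD2DEG
        values = c + wrap_angle(deg - c)      # branch of the window center
        windows.append(
            UmbrellaWindow(
                center=float(c), force_constant=force_constant,
                temperature=model.temperature,
                series=AngleSeries(dt=dt_store, values=values,
                                   label=f"window {c:g} deg"),
            )
        )
    rate = accepts / attempts if attempts else float("nan")
    return CampaignResult(
        windows=WindowSet(windows=windows),
        acceptance_rate=float(rate), n_attempts=int(attempts),
    )


@dataclass
class OracleResult:
    mean: float               # ps
    std_err: float            # ps
    times: np.ndarray         # ps
    n_censored: int


def first_passage_oracle(
    model: ModelSystem,
    reflect_at: float,
    absorb_at: float,
    n_walkers: int = 10_000,
    dt: float = 0.01,
    max_steps: int = 20_000_000,
    seed: int = 0,
    start: float | None = None,
) -> OracleResult:
    """Brute-force mean first passage time by direct Langevin simulation.

    Walkers start at ``start`` (deg; default the reflecting boundary), are
    mirrored at the reflecting boundary and stop on first crossing of the
    absorbing one.  Walkers hitting the step cap count as censored; more than
    1% censored raises.
    """
    if reflect_at == absorb_at:
        return OracleResult(0.0, 0.0, np.zeros(n_walkers), 0)
    fprime, d_tab, dprime = model.tables()
    beta = model.beta
    drift = beta * float(d_tab.max()) * float(np.abs(fprime).max()) * dt
    if drift > 0.2:
        raise StabilityError(f"oracle per-step drift {drift:.3f} rad > 0.2")
    x0 = reflect_at if start is None else start
    times, censored = _kernels.first_passage(
        x0 * DEG2RAD, reflect_at * DEG2RAD, absorb_at * DEG2RAD,
        int(n_walkers), dt, beta, fprime, d_tab, dprime,
        int(max_steps), int(seed) % (2**31 - 1),
    )
    if censored > 0.01 * n_walkers:
        raise RuntimeError(
            f"{censored}/{n_walkers} walkers censored at the step cap; "
            "raise max_steps"
        )
    return OracleResult(
        mean=float(times.mean()),
        std_err=float(times.std(ddof=1) / np.sqrt(n_walkers)),
        times=times, n_censored=int(censored),
    )


# -- restraint-perturbation input ---------------------------------------------


@dataclass
class AuxiliaryHarmonic:
    """Harmonic reference model for an auxiliary distance coordinate."""

    force_constant: float     # kcal mol^-1 A^-2
    center: float             # Angstrom
    diffusivity: float = 0.1  # A^2/ps


def make_perturbation_series(
    aux: AuxiliaryHarmonic,
    restraint,
    temperature: float = 300.0,
    n_samples: int = 100_000,
    dt: float = 1e-3,
    stride: int = 5,
    seed: int = 0,
):
    """Simulate the restrained reference ensemble of the auxiliary coordinate
    and return the restraint-removal perturbation series dU = -U_restraint.

    The analytic ground truth is available from
    :func:`analytic_restraint_delta_f`.
    """
    from flipkin.fep import PerturbationSeries, flat_bottom_energy

    beta = 1.0 / kt_kcal(temperature)
    frames = _kernels.harmonic_restraint_traj(
        aux.center, 10_000, int(n_samples), int(stride), dt, beta,
        aux.force_constant, aux.center, restraint.lower, restraint.upper,
        restraint.force_constant, aux.diffusivity, int(seed) % (2**31 - 1),
    )
    du = -flat_bottom_energy(frames, restraint)
    return PerturbationSeries(delta_u=du, temperature=temperature,
                              label="restraint removal")


def analytic_restraint_delta_f(
    aux: AuxiliaryHarmonic, restraint, temperature: float = 300.0
) -> float:
    """Exact restraint-removal free energy by quadrature of both partition
    functions (kcal/mol)."""
    from flipkin.fep import flat_bottom_energy

    kt = kt_kcal(temperature)
    sigma = np.sqrt(kt / aux.force_constant)
    lo, hi = aux.center - 12 * sigma, aux.center + 12 * sigma

    def u_ref(x):
        return (0.5 * aux.force_constant * (x - aux.center) ** 2
                + flat_bottom_energy(x, restraint))

    def u_target(x):
        return 0.5 * aux.force_constant * (x - aux.center) ** 2

    z_ref, _ = quad(lambda x: np.exp(-u_ref(x) / kt), lo, hi, limit=200)
    z_tgt, _ = quad(lambda x: np.exp(-u_target(x) / kt), lo, hi, limit=200)
    return float(-kt * np.log(z_tgt / z_ref))


# -- campaign serialization ----------------------------------------------------


def write_campaign(
    out_dir: str | Path,
    result: CampaignResult,
    model: ModelSystem | None = None,
    seed: int | None = None,
) -> None:
    """Write window series in the text dialect plus a window-metadata file and
    (when the model is given) a ground-truth sidecar for test harnesses."""
    from flipkin.umbrella import write_window_series
    import yaml

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = []
    for i, w in enumerate(result.windows):
        name = f"window_{i:04d}.dat"
        write_window_series(out / name, w)
        meta.append({
            "path": name, "center": float(w.center),
            "force_constant": float(w.force_constant),
            "temperature": float(w.temperature),
        })
    with open(out / "windows.yaml", "w") as fh:
        yaml.safe_dump(
            {"windows": meta, "acceptance_rate": result.acceptance_rate},
            fh, sort_keys=False,
        )
    if model is not None:
        sidecar = model.to_dict()
        sidecar["seed"] = seed
        with open(out / "ground_truth.json", "w") as fh:
            json.dump(sidecar, fh, indent=2)
            fh.write("\n")
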