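"""The full iterative inference procedure and its diagnostics.

Branch I (once): choose theta* from increment asymmetry, detect jumps,
measure Gamma_C and Q_C.  Branch II (once): estimate D by the segment
noise-intensity scan and form the initial drift guess F1 from the stationary
Fokker-Planck inversion.  Branch III (iterate): with the current drift,
calculate the FP statistics (Gamma_A, Q_A), solve for lambda, demix and
deconvolve Q_B, and re-estimate the drift from the stationary
Chapman-Kolmogorov balance; repeat until lambda and F stop moving.

Also here: goodness-of-fit diagnostics (PDF / ACF / PSD comparison between
the data and a simulation of the fitted model) and the Einstein-Markov
timescale scan used to pick a sampling interval on which the data are
approximately Markov.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from . import detection, diffusion_drift, fp_statistics, jump_inference
from .grids import GriddedDensity, GriddedFunction, kde_density
from .simulator import JumpDiffusionModel, UniformTimeSeries

logger = logging.getLogger("jumpsde")


class ThresholdFallbackWarning(UserWarning):
    pass


@dataclass
class FitConfig:
    """Every tunable of the inference pipeline, with defaults."""

    theta_star: float | None = None  # user-supplied threshold overrides branch I
    n_state: int = 512  # minimum state-grid size; refined so dy <~ sigma_inc/4
    max_state: int = 4096
    n_y0: int = 64
    n_amplitude: int = 512
    state_floor: float = 1e-6
    kde_bw_state: float | None = None
    kde_bw_amplitude: float | None = None
    theta_grid_size: int = 200
    min_truncated: int = 50
    smooth_window: int = 5
    i_max_cap: int = 10
    duration_tail_tol: float = 1e-3
    max_iterations: int = 20
    tol_lambda: float = 1e-3
    tol_drift: float = 1e-2
    deconv_tol: float = 1e-4
    deconv_max_iter: int = 500
    noise_n_theta: int = 30
    noise_q_low: float = 0.90
    noise_q_high: float = 0.9999
    jta_top_fraction: float = 1.0
    jta_deriv_threshold: float = 0.05
    acf_max_lag: int | None = None
    psd_segments: int = 8

    @classmethod
    def from_file(cls, path) -> "FitConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        unknown = set(raw) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**known)


@dataclass
class IterationRecord:
    iteration: int
    gamma_A: float
    lambda_hat: float
    drift: GriddedFunction
    clipped_mass: float
    deconv_residual: float


@dataclass
class FitResult:
    """The fitted model, the per-iteration history, and the branch-I/II data."""

    model_hat: JumpDiffusionModel
    theta_star: float
    converged: bool
    n_iterations: int
    pure_diffusion: bool
    history: list[IterationRecord]
    pool: detection.JumpPool
    Q_C: GriddedDensity
    P_X: GriddedDensity
    noise_scan: diffusion_drift.NoiseScan
    F1: GriddedFunction
    fp: fp_statistics.FPStatistics | None
    demix: jump_inference.DemixResult | None

    @property
    def lambda_hat(self) -> float:
        return self.model_hat.jump_rate

    @property
    def D_hat(self) -> float:
        return self.model_hat.noise_intensity

    def to_dict(self) -> dict:
        return {
            "D_hat": self.D_hat,
            "lambda_hat": self.lambda_hat,
            "lambda_se": self.demix.lambda_se if self.demix else None,
            "theta_star": self.theta_star,
            "gamma_C": self.pool.gamma_C,
            "gamma_A": self.fp.gamma_A if self.fp else None,
            "converged": self.converged,
            "n_iterations": self.n_iterations,
            "pure_diffusion": self.pure_diffusion,
            "Phi": self.noise_scan.Phi,
            "history": [
                {
                    "iteration": h.iteration,
                    "gamma_A": h.gamma_A,
                    "lambda_hat": h.lambda_hat,
                    "clipped_mass": h.clipped_mass,
                    "deconv_residual": h.deconv_residual,
                }
                for h in self.history
            ],
        }


def _drift_change(F_new: GriddedFunction, F_old: GriddedFunction) -> float:
    ref = max(float(np.nanmax(np.abs(F_old.y))), 1e-300)
    new_on_old = np.interp(F_old.x, F_new.x, F_new.y)
    return float(np.nanmax(np.abs(new_on_old - F_old.y))) / ref


def fit(ts: UniformTimeSeries, config: FitConfig | None = None) -> FitResult:
    """Run the full iterative jump-diffusion inference on one time series."""
    cfg = config or FitConfig()
    dt = ts.dt

    # ---------------- branch I: threshold, detection, Gamma_C, Q_C --------
    theta_star = cfg.theta_star
    pure_diffusion_forced = False
    if theta_star is None:
        scan = detection.truncated_mean_curves(
            ts, n_theta=cfg.theta_grid_size, min_count=cfg.min_truncated
        )
        try:
            theta_star = detection.select_threshold(scan, cfg.smooth_window)
        except detection.ThresholdSelectionError as err:
            warnings.warn(
                f"threshold selection failed ({err}); falling back to a "
                "pure-diffusion fit",
                ThresholdFallbackWarning,
                stacklevel=2,
            )
            pure_diffusion_forced = True
            # a nominal threshold so the noise scan machinery still works
            theta_star = float(np.quantile(ts.increments[ts.increments > 0], 0.99))
    logger.info("theta* = %.6g", theta_star)

    pool = detection.detect_jumps(ts, theta_star)
    amplitude_grid = detection.default_amplitude_grid(pool, cfg.n_amplitude)

    # ---------------- branch II: noise intensity and initial drift --------
    noise_scan = diffusion_drift.noise_intensity_scan(
        ts,
        n_theta=cfg.noise_n_theta,
        q_low=cfg.noise_q_low,
        q_high=cfg.noise_q_high,
        top_fraction=cfg.jta_top_fraction,
        deriv_threshold=cfg.jta_deriv_threshold,
    )
    D_hat = noise_scan.D_hat
    logger.info("D_hat = %.6g (Phi = %.4g s)", D_hat, noise_scan.Phi)

    # Q_C bandwidth: Silverman on the pooled amplitudes, but never wider than
    # the diffusive one-step scale -- on a bimodal pool (sharp FP spike plus a
    # broad jump bulk, Case-2-like) Silverman is set by the bulk and would
    # smear the FP structure the demixing needs to cancel
    if cfg.kde_bw_amplitude is not None:
        bw_amp = cfg.kde_bw_amplitude
    else:
        a = pool.amplitudes
        iqr = np.subtract(*np.percentile(a, [75, 25]))
        spread = min(a.std(), iqr / 1.349) if iqr > 0 else a.std()
        silverman = 0.9 * spread * a.size ** (-0.2)
        sigma_step = float(np.sqrt(2.0 * D_hat * dt))
        da = float(amplitude_grid[1] - amplitude_grid[0])
        bw_amp = float(np.clip(silverman, max(0.5 * sigma_step, 2 * da), 1.5 * sigma_step))
    Q_C = detection.estimate_QC(pool, amplitude_grid, bandwidth=bw_amp)

    # state grid fine enough to resolve the one-step propagator
    sigma_inc = np.sqrt(2.0 * D_hat * dt)
    span = ts.values.max() - ts.values.min()
    n_state = int(np.clip(np.ceil(4.0 * span / sigma_inc), cfg.n_state, cfg.max_state))
    # the drift inversion differentiates P_X, so the bandwidth follows the
    # derivative-optimal rate n^(-1/7) rather than Silverman's n^(-1/5)
    if cfg.kde_bw_state is not None:
        bw_state = cfg.kde_bw_state
    else:
        from statsmodels.nonparametric.bandwidths import bw_silverman

        bw_state = float(bw_silverman(ts.values)) * ts.n ** (2.0 / 35.0)
    grid, P_X = fp_statistics.StateGrid.from_samples(
        ts.values, n=n_state, floor=cfg.state_floor, bandwidth=bw_state
    )
    F1 = diffusion_drift.initial_drift(P_X, D_hat, floor=cfg.state_floor)

    if pure_diffusion_forced:
        model = JumpDiffusionModel(
            drift=F1, noise_intensity=D_hat, jump_rate=0.0, jump_dist=None, dt=dt
        )
        return FitResult(
            model_hat=model,
            theta_star=theta_star,
            converged=True,
            n_iterations=0,
            pure_diffusion=True,
            history=[],
            pool=pool,
            Q_C=Q_C,
            P_X=P_X,
            noise_scan=noise_scan,
            F1=F1,
            fp=None,
            demix=None,
        )

    # ---------------- branch III: the iterative loop ----------------------
    F_hat = F1
    lambda_prev = None
    history: list[IterationRecord] = []
    converged = False
    fp = None
    demix = None
    for it in range(1, cfg.max_iterations + 1):
        fp = fp_statistics.fp_amplitude_distribution(
            F_hat,
            D_hat,
            dt,
            theta_star,
            P_X,
            amplitude_grid,
            n_y0=cfg.n_y0,
            i_max_cap=cfg.i_max_cap,
            tail_tol=cfg.duration_tail_tol,
        )
        demix = jump_inference.extract_true_jump_statistics(
            Q_C,
            fp.Q_A,
            fp.gamma_A,
            pool.gamma_C,
            D_hat,
            dt,
            n_detected=pool.n_events,
            duration=ts.duration,
            deconv_max_iter=cfg.deconv_max_iter,
            deconv_tol=cfg.deconv_tol,
            kde_bandwidth=bw_amp,
            # early iterations start from the flat F1, which can badly
            # overestimate Gamma_A; let the loop clip and refine
            max_clip_fraction=0.95,
        )
        lam = demix.lambda_hat
        if demix.pure_diffusion:
            logger.info("iteration %d: lambda clipped to 0 -> pure diffusion", it)
            history.append(
                IterationRecord(it, fp.gamma_A, 0.0, F1, demix.clipped_mass, 0.0)
            )
            model = JumpDiffusionModel(
                drift=F1, noise_intensity=D_hat, jump_rate=0.0, jump_dist=None, dt=dt
            )
            return FitResult(
                model_hat=model,
                theta_star=theta_star,
                converged=True,
                n_iterations=it,
                pure_diffusion=True,
                history=history,
                pool=pool,
                Q_C=Q_C,
                P_X=P_X,
                noise_scan=noise_scan,
                F1=F1,
                fp=fp,
                demix=demix,
            )

        F_new = diffusion_drift.drift_from_chapman_kolmogorov(
            P_X, D_hat, lam, demix.Q_B_hat, floor=cfg.state_floor
        )
        d_change = _drift_change(F_new, F_hat)
        l_change = abs(lam - lambda_prev) / lam if lambda_prev else np.inf
        history.append(
            IterationRecord(
                it, fp.gamma_A, lam, F_new, demix.clipped_mass, demix.residual_norm
            )
        )
        logger.info(
            "iteration %d: Gamma_A=%.5g lambda=%.5g dF=%.3g dlam=%.3g",
            it,
            fp.gamma_A,
            lam,
            d_change,
            l_change,
        )
        F_hat = F_new
        lambda_prev = lam
        if l_change < cfg.tol_lambda and d_change < cfg.tol_drift:
            converged = True
            break

    if not converged:
        warnings.warn(
            "iteration limit reached without convergence; returning the last "
            "iterate",
            stacklevel=2,
        )
    if demix is not None and demix.clipped_mass > 0.2:
        warnings.warn(
            f"{100 * demix.clipped_mass:.0f}% of the demixed jump component "
            "was negative at the final iteration; Gamma estimates may be "
            "unreliable",
            stacklevel=2,
        )
    model = JumpDiffusionModel(
        drift=F_hat,
        noise_intensity=D_hat,
        jump_rate=lambda_prev,
        jump_dist=demix.Q_B_hat,
        dt=dt,
    )
    return FitResult(
        model_hat=model,
        theta_star=theta_star,
        converged=converged,
        n_iterations=len(history),
        pure_diffusion=False,
        history=history,
        pool=pool,
        Q_C=Q_C,
        P_X=P_X,
        noise_scan=noise_scan,
        F1=F1,
        fp=fp,
        demix=demix,
    )


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------


@dataclass
class Diagnostics:
    """PDF / ACF / PSD comparison between data and a fitted-model simulation."""

    pdf_grid: np.ndarray
    pdf_data: np.ndarray
    pdf_fit: np.ndarray
    pdf_nrmse: float
    acf_lags: np.ndarray
    acf_data: np.ndarray
    acf_fit: np.ndarray
    psd_freqs: np.ndarray
    psd_data: np.ndarray
    psd_fit: np.ndarray
    psd_data_ci: tuple[np.ndarray, np.ndarray]
    psd_fit_ci: tuple[np.ndarray, np.ndarray]


def compare_pdf_acf_psd(
    ts_data: UniformTimeSeries,
    ts_fit: UniformTimeSeries,
    max_lag: int | None = None,
    n_psd_segments: int = 8,
    n_pdf_grid: int = 512,
) -> Diagnostics:
    """Goodness-of-fit diagnostics between the data and a refit simulation.

    The PDF root-mean-square error is normalized by the range of the data
    values; the ACF is the biased, normalized autocorrelation; the PSD uses
    Welch averaging with 50%-overlap segments and chi-squared 95% intervals.
    """
    if abs(ts_data.dt - ts_fit.dt) > 1e-12:
        raise ValueError("the two series must share the sampling interval")
    from scipy.signal import welch
    from scipy.stats import chi2
    from statsmodels.tsa.stattools import acf as sm_acf

    lo = min(ts_data.values.min(), ts_fit.values.min())
    hi = max(ts_data.values.max(), ts_fit.values.max())
    grid = np.linspace(lo, hi, n_pdf_grid)
    p_data = kde_density(ts_data.values, grid).y
    p_fit = kde_density(ts_fit.values, grid).y
    data_range = float(ts_data.values.max() - ts_data.values.min())
    nrmse = float(np.sqrt(np.mean((p_data - p_fit) ** 2))) / data_range

    if max_lag is None:
        max_lag = min(1000, ts_data.n // 10)
    acf_data = sm_acf(ts_data.values, nlags=max_lag, fft=True)
    acf_fit = sm_acf(ts_fit.values, nlags=max_lag, fft=True)

    nperseg = max(8, int(2 * ts_data.n / (n_psd_segments + 1)))
    fs = 1.0 / ts_data.dt
    freqs, psd_data = welch(ts_data.values, fs=fs, nperseg=nperseg)
    _, psd_fit = welch(ts_fit.values, fs=fs, nperseg=min(nperseg, ts_fit.n))
    dof = 2 * n_psd_segments
    lo_f = dof / chi2.ppf(0.975, dof)
    hi_f = dof / chi2.ppf(0.025, dof)

    return Diagnostics(
        pdf_grid=grid,
        pdf_data=p_data,
        pdf_fit=p_fit,
        pdf_nrmse=nrmse,
        acf_lags=np.arange(max_lag + 1),
        acf_data=acf_data,
        acf_fit=acf_fit,
        psd_freqs=freqs,
        psd_data=psd_data,
        psd_fit=psd_fit,
        psd_data_ci=(psd_data * lo_f, psd_data * hi_f),
        psd_fit_ci=(psd_fit * lo_f, psd_fit * hi_f),
    )


# ---------------------------------------------------------------------------
# Einstein-Markov timescale
# ---------------------------------------------------------------------------


@dataclass
class MarkovScan:
    """chi^2(tau) of the Chapman-Kolmogorov consistency test and its minimizer."""

    tau_grid: np.ndarray  # in steps
    chi2: np.ndarray
    tau_EM_steps: int
    dt: float
    n_bins: int

    @property
    def tau_EM(self) -> float:
        return self.tau_EM_steps * self.dt


def _chi2_markov(x: np.ndarray, tau: int, edges: np.ndarray) -> float:
    x1 = x[:-2 * tau : 1]
    x2 = x[tau:-tau]
    x3 = x[2 * tau :]
    n = min(x1.size, x2.size, x3.size)
    x1, x2, x3 = x1[:n], x2[:n], x3[:n]
    H, _ = np.histogramdd(np.column_stack([x1, x2, x3]), bins=(edges, edges, edges))
    p123 = H / H.sum()

    p12 = p123.sum(axis=2)  # joint of (x1, x2)
    p23 = p123.sum(axis=0)  # joint of (x2, x3)
    p2 = p123.sum(axis=(0, 2))
    with np.errstate(divide="ignore", invalid="ignore"):
        cond = np.where(p2[:, None] > 0, p23 / np.where(p2[:, None] > 0, p2[:, None], 1.0), 0.0)
    q123 = p12[:, :, None] * cond[None, :, :]

    centers = 0.5 * (edges[1:] + edges[:-1])
    widths = np.diff(edges)
    vol = widths[0] ** 3  # uniform bins

    def _trace_cov(mass: np.ndarray) -> float:
        tot = mass.sum()
        if tot <= 0:
            return 0.0
        m = mass / tot
        tr = 0.0
        for axis in range(3):
            marg = m.sum(axis=tuple(a for a in range(3) if a != axis))
            mu = np.sum(centers * marg)
            tr += np.sum((centers - mu) ** 2 * marg)
        return tr

    sigma2 = _trace_cov(p123) + _trace_cov(q123)
    if sigma2 <= 0:
        return 0.0
    return float(np.sum((p123 - q123) ** 2) / (sigma2 * vol))


def einstein_markov_timescale(
    ts: UniformTimeSeries,
    tau_grid: np.ndarray | None = None,
    n_bins: int = 20,
    central_range: float = 0.99,
) -> MarkovScan:
    """Scan the Chapman-Kolmogorov chi^2(tau) over candidate lags and return
    its minimizer, the lag at which the series is approximately Markov.

    Histograms use ``n_bins`` uniform bins per axis over the central
    ``central_range`` quantile range of the data.
    """
    if tau_grid is None:
        tau_grid = np.arange(1, 31)
    tau_grid = np.asarray(tau_grid, dtype=int)
    if np.any(tau_grid < 1):
        raise ValueError("lags must be >= 1 steps")
    x = ts.values
    q = (1.0 - central_range) / 2.0
    lo, hi = np.quantile(x, [q, 1.0 - q])
    edges = np.linspace(lo, hi, n_bins + 1)

    n_triples = ts.n - 2 * int(tau_grid.max())
    if n_triples < 10 * n_bins**2:
        warnings.warn(
            "3-way histograms are sparsely occupied at the largest lag; the "
            "chi^2 scan may be noisy",
            stacklevel=2,
        )

    chi = np.array([_chi2_markov(x, int(t), edges) for t in tau_grid])
    best = int(np.argmin(chi))
    return MarkovScan(
        tau_grid=tau_grid,
        chi2=chi,
        tau_EM_steps=int(tau_grid[best]),
        dt=ts.dt,
        n_bins=n_bins,
    )


def downsample(ts: UniformTimeSeries, factor: int) -> UniformTimeSeries:
    """Keep every ``factor``-th sample; the sampling interval scales by
    ``factor``.  Used to re-express data at the Einstein-Markov timescale."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    return UniformTimeSeries(values=ts.values[::factor].copy(), dt=ts.dt * factor)
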