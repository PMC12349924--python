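"""Trajectory analysis: density maps, pore area, cargo penetration, MSD,
lipid diffusion, and the membrane elastic moduli.

Elasticity estimators
---------------------
Bending stiffness follows the height-fluctuation route: the bilayer
midplane is sampled onto a lateral grid, Fourier transformed, and the
long-wavelength modes fitted to the continuum spectrum

    <|h(q)|^2> = k_B T / (A kappa q^4)

(amplitudes normalized so that h_q = FFT2(h)/Ncells), generalized to
the tension + bending form sigma_eff q^2 + kappa q^4 because small
patches keep an effective fluctuation tension.  Modes with
q >= 2 pi / (6 sigma) are excluded (protrusion regime).  The stretching
modulus uses projected-area fluctuations of the tensionless ensemble,
K_A = k_B T <A> / Var(A).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .forcefield import BeadKind
from .system import Frame, Trajectory


class AnalysisError(ValueError):
    pass


@dataclass
class ObservableSeries:
    """A named time series in reduced units."""

    name: str
    times: np.ndarray
    values: np.ndarray
    units: str = ""
    replica: int = 0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.times) != len(self.values):
            raise AnalysisError("times and values must have equal length")
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise AnalysisError("times must be strictly increasing")


def _lipid_mask_frame(frame: Frame) -> np.ndarray:
    k = frame.kinds
    return ((k == BeadKind.HEAD) | (k == BeadKind.TAIL1)
            | (k == BeadKind.TAIL2) | (k == BeadKind.RECEPTOR_HEAD))


# ---------------------------------------------------------------------------
# density / pores / penetration
# ---------------------------------------------------------------------------

def lipid_density_map(frame: Frame, cell: float = 2.0) -> tuple[np.ndarray, float]:
    """2D number density of lipid beads on a lateral grid.

    Returns ``(grid, cell_area)``; ``grid.sum() * cell_area`` equals the
    lipid bead count.
    """
    if not 1.0 <= cell <= 5.0:
        raise AnalysisError("cell size must be within [1, 5] sigma")
    Lx, Ly = float(frame.box[0]), float(frame.box[1])
    nx = max(1, int(round(Lx / cell)))
    ny = max(1, int(round(Ly / cell)))
    mask = _lipid_mask_frame(frame)
    xy = frame.positions[mask][:, :2]
    H, _, _ = np.histogram2d(
        xy[:, 0] % Lx, xy[:, 1] % Ly, bins=(nx, ny),
        range=[[0.0, Lx], [0.0, Ly]])
    cell_area = (Lx / nx) * (Ly / ny)
    return H / cell_area, cell_area


def pore_area(density: np.ndarray, cell_area: float,
              threshold_fraction: float = 0.25,
              reference_density: float | None = None) -> dict:
    """Depleted-membrane area from a density grid.

    Cells below ``threshold_fraction`` of the reference (default: grid
    mean) density are pore cells; 4-connected components are summed.
    Returns total area, largest-component area and component count.
    """
    if density.size == 0:
        raise AnalysisError("degenerate (empty) density grid")
    if not 0.0 < threshold_fraction < 1.0:
        raise AnalysisError("threshold_fraction must be in (0, 1)")
    ref = reference_density if reference_density is not None \
        else float(density.mean())
    holes = density < threshold_fraction * ref
    labels, n = ndimage.label(holes)  # default structure = 4-connectivity
    if n == 0:
        return {"total_area": 0.0, "largest_area": 0.0, "n_components": 0,
                "threshold_fraction": threshold_fraction}
    sizes = ndimage.sum_labels(holes, labels, index=np.arange(1, n + 1))
    return {"total_area": float(sizes.sum() * cell_area),
            "largest_area": float(sizes.max() * cell_area),
            "n_components": int(n),
            "threshold_fraction": threshold_fraction}


def leaflet_planes(frame: Frame) -> tuple[float, float]:
    """(upper, lower) mean head-bead z, split at the lipid median z."""
    k = frame.kinds
    heads = (k == BeadKind.HEAD) | (k == BeadKind.RECEPTOR_HEAD)
    lip = _lipid_mask_frame(frame)
    if not lip.any():
        raise AnalysisError("no lipids in frame")
    zmid = float(np.median(frame.positions[lip][:, 2]))
    z = frame.positions[heads][:, 2]
    upper = z[z > zmid]
    lower = z[z <= zmid]
    if len(upper) == 0 or len(lower) == 0:
        raise AnalysisError("could not identify both leaflets")
    return float(upper.mean()), float(lower.mean())


def penetrated_count(frame: Frame, margin: float = 1.0) -> int:
    """Cargo beads on the trans side: z below the lower head plane minus
    *margin* (uses unwrapped z so repeated crossings are not double
    counted by the periodic image)."""
    _, lower = leaflet_planes(frame)
    cargo = frame.kinds == BeadKind.CARGO
    z = frame.unwrapped[cargo][:, 2]
    return int(np.count_nonzero(z < lower - margin))


def penetrated_series(traj: Trajectory, margin: float = 1.0,
                      cumulative: bool = True) -> ObservableSeries:
    counts = [penetrated_count(fr, margin) for fr in traj.frames]
    if cumulative:
        counts = np.maximum.accumulate(counts)
    return ObservableSeries("penetrated_count", traj.times, counts,
                            units="count", metadata={"margin": margin,
                                                     "cumulative": cumulative})


def pore_area_series(traj: Trajectory, cell: float = 2.0,
                     threshold_fraction: float = 0.25,
                     which: str = "total_area") -> ObservableSeries:
    vals = []
    for fr in traj.frames:
        grid, ca = lipid_density_map(fr, cell)
        vals.append(pore_area(grid, ca, threshold_fraction)[which])
    return ObservableSeries("pore_area", traj.times, vals, units="sigma^2",
                            metadata={"cell": cell,
                                      "threshold_fraction": threshold_fraction,
                                      "which": which})


# ---------------------------------------------------------------------------
# MSD and diffusion
# ---------------------------------------------------------------------------

def msd(traj: Trajectory, selection: np.ndarray,
        axis_mask: tuple[int, int, int] = (1, 1, 1),
        max_lag_fraction: float = 0.5) -> ObservableSeries:
    """Mean square displacement over beads and sliding time origins.

    *selection* is a boolean mask or index array over beads of frame 0;
    *axis_mask* picks the displacement components (e.g. ``(0, 0, 1)`` for
    the transmembrane direction).  Uses unwrapped coordinates.
    """
    if len(traj.frames) < 2:
        raise AnalysisError("need at least two frames for an MSD")
    sel = np.asarray(selection)
    if sel.dtype == bool:
        sel = np.where(sel)[0]
    if len(sel) == 0:
        raise AnalysisError("empty selection")
    am = np.asarray(axis_mask, dtype=bool)
    X = np.stack([fr.unwrapped[sel][:, am] for fr in traj.frames])  # (T,n,d)
    T = X.shape[0]
    times = traj.times
    max_lag = max(1, int(T * max_lag_fraction))
    lags = np.arange(1, max_lag + 1)
    out = np.empty(len(lags))
    for li, lag in enumerate(lags):
        d = X[lag:] - X[:-lag]
        out[li] = float((d ** 2).sum(axis=2).mean())
    dt = float(np.mean(np.diff(times)))
    return ObservableSeries("msd", lags * dt, out, units="sigma^2",
                            metadata={"axes": tuple(int(a) for a in am),
                                      "n_beads": len(sel)})


def diffusion_coefficient(series: ObservableSeries, dimensionality: int,
                          fit_window: tuple[float, float] | None = None
                          ) -> dict:
    """Least-squares slope of the MSD over *fit_window* divided by
    ``2 * dimensionality``."""
    t, y = series.times, series.values
    if fit_window is not None:
        m = (t >= fit_window[0]) & (t <= fit_window[1])
        t, y = t[m], y[m]
    if len(t) < 2:
        raise AnalysisError("fit window must contain at least two points")
    slope, intercept = np.polyfit(t, y, 1)
    D = slope / (2.0 * dimensionality)
    return {"D": float(D), "slope": float(slope),
            "intercept": float(intercept),
            "warning": "non-positive slope" if slope <= 0 else None}


def lipid_lateral_diffusion(traj: Trajectory,
                            fit_window: tuple[float, float] | None = None
                            ) -> dict:
    """Lateral (x, y) diffusion coefficient of lipid molecules.

    Tracks head beads; D is per molecule and reported in sigma^2/tau.
    The default fit window is the second half of the lag range, past the
    short-time ballistic/caging regime.
    """
    k0 = traj.frames[0].kinds
    heads = (k0 == BeadKind.HEAD) | (k0 == BeadKind.RECEPTOR_HEAD)
    series = msd(traj, heads, axis_mask=(1, 1, 0))
    if fit_window is None:
        tmax = series.times[-1]
        fit_window = (0.3 * tmax, tmax)
    return diffusion_coefficient(series, 2, fit_window) | {
        "msd": series, "fit_window": fit_window}


# ---------------------------------------------------------------------------
# height field and bending stiffness
# ---------------------------------------------------------------------------

@dataclass
class HeightField:
    grid: np.ndarray          # (nx, ny) midplane heights
    cell: tuple[float, float]
    time: float
    n_empty: int = 0          # cells interpolated from neighbours


def height_field(frame: Frame, n_cells: int = 8) -> HeightField:
    """Midplane height of the bilayer on an ``n_cells x n_cells`` grid.

    Uses all lipid beads; empty cells are filled by iterative neighbour
    averaging and counted in ``n_empty``.
    """
    Lx, Ly = float(frame.box[0]), float(frame.box[1])
    mask = _lipid_mask_frame(frame)
    p = frame.positions[mask]
    ix = np.clip((p[:, 0] % Lx) / Lx * n_cells, 0, n_cells - 1e-9).astype(int)
    iy = np.clip((p[:, 1] % Ly) / Ly * n_cells, 0, n_cells - 1e-9).astype(int)
    sums = np.zeros((n_cells, n_cells))
    counts = np.zeros((n_cells, n_cells))
    np.add.at(sums, (ix, iy), p[:, 2])
    np.add.at(counts, (ix, iy), 1.0)
    grid = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    n_empty = int(np.isnan(grid).sum())
    while np.isnan(grid).any():
        nanmask = np.isnan(grid)
        filled = np.where(nanmask, 0.0, grid)
        have = (~nanmask).astype(float)
        ssum = np.zeros_like(grid)
        scount = np.zeros_like(grid)
        for shift in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            ssum += np.roll(filled, shift, axis=(0, 1))
            scount += np.roll(have, shift, axis=(0, 1))
        newvals = np.where(scount > 0, ssum / np.maximum(scount, 1), np.nan)
        grid = np.where(nanmask, newvals, grid)
        if np.isnan(grid).all():
            raise AnalysisError("empty height field")
    grid = grid - grid.mean()
    return HeightField(grid, (Lx / n_cells, Ly / n_cells), 0.0, n_empty)


def fluctuation_spectrum(traj: Trajectory, n_cells: int = 8,
                         skip: int = 0) -> dict:
    """Frame-averaged ``<|h_q|^2>`` with the q-grid of the mean box."""
    frames = traj.frames[skip:]
    if not frames:
        raise AnalysisError("no frames after skip")
    acc = None
    areas = []
    for fr in frames:
        hf = height_field(fr, n_cells)
        hq = np.fft.fft2(hf.grid) / (n_cells * n_cells)
        p2 = np.abs(hq) ** 2
        acc = p2 if acc is None else acc + p2
        areas.append(float(fr.box[0] * fr.box[1]))
    S = acc / len(frames)
    A = float(np.mean(areas))
    L = np.sqrt(A)
    kx = np.fft.fftfreq(n_cells) * n_cells * 2 * np.pi / L
    ky = np.fft.fftfreq(n_cells) * n_cells * 2 * np.pi / L
    QX, QY = np.meshgrid(kx, ky, indexing="ij")
    q = np.sqrt(QX**2 + QY**2)
    return {"S": S, "q": q, "area": A, "n_frames": len(frames)}


def bending_stiffness(traj: Trajectory, n_cells: int = 8,
                      temperature: float = 1.1, skip: int = 0,
                      q_max: float = 2 * np.pi / 6.0,
                      min_frames: int = 50,
                      n_bootstrap: int = 200, seed: int = 0) -> dict:
    """Helfrich bending modulus from the low-q height-mode spectrum.

    Fits the inverse spectrum to the tension + bending form,
    ``k_B T / (A S(q)) = sigma_eff q^2 + kappa q^4``, over mode shells
    with ``0 < q < q_max`` (sinc^2-deconvolved for the grid's box
    filter); the block bootstrap gives the standard error.  A log-log
    spectrum slope far from -4 flags a bending-dominated-regime
    violation.
    """
    frames = traj.frames[skip:]
    if len(frames) < min_frames:
        raise AnalysisError(
            f"need at least {min_frames} frames, got {len(frames)}")
    per_frame = []
    areas = []
    for fr in frames:
        hf = height_field(fr, n_cells)
        hq = np.fft.fft2(hf.grid) / (n_cells * n_cells)
        per_frame.append(np.abs(hq) ** 2)
        areas.append(float(fr.box[0] * fr.box[1]))
    per_frame = np.asarray(per_frame)
    A = float(np.mean(areas))
    L = np.sqrt(A)
    k1 = np.fft.fftfreq(n_cells) * n_cells * 2 * np.pi / L
    QX, QY = np.meshgrid(k1, k1, indexing="ij")
    q = np.sqrt(QX**2 + QY**2)
    sel = (q > 1e-12) & (q < q_max)
    if not sel.any():
        raise AnalysisError("no modes below q_max; increase the box or grid")
    qs = q[sel]
    # grid binning is a box filter: deconvolve each mode by its sinc^2
    # pixel window before fitting, else edge modes bias kappa high
    cell = L / n_cells
    W = (np.sinc(QX * cell / (2 * np.pi)) *
         np.sinc(QY * cell / (2 * np.pi))) ** 2
    Wsel = W[sel]

    # group modes into |q| shells (averaging equal-|q| modes stabilizes
    # the fit; per-shell errors come from consecutive frame blocks)
    shell_q, shell_inv = np.unique(np.round(qs, 9), return_inverse=True)
    n_shell = len(shell_q)

    def shell_means(S2d_sel):
        flat = S2d_sel / Wsel
        sums = np.bincount(shell_inv, weights=flat, minlength=n_shell)
        cnts = np.bincount(shell_inv, minlength=n_shell)
        return sums / cnts

    n_blocks = min(10, max(2, len(per_frame) // 20))
    block_shells = np.array([
        shell_means(b.mean(axis=0)[sel])
        for b in np.array_split(per_frame, n_blocks)])
    S_shell = shell_means(per_frame.mean(axis=0)[sel])
    S_shell_se = block_shells.std(axis=0) / np.sqrt(n_blocks)

    def fit_of(S_sh):
        """Two-parameter Helfrich fit kBT/(A S) = sigma q^2 + kappa q^4.

        Small tensionless patches keep an effective fluctuation tension
        even at zero frame tension; a pure q^-4 fit would absorb it into
        kappa and bias high.  Highest-q shells falling > 2.5 SE below
        the fit (the protrusion break) are trimmed, at most two.
        """
        keep = np.ones(n_shell, dtype=bool)
        beta = np.zeros(2)
        while True:
            y = temperature / (A * S_sh[keep])
            y_se = y * S_shell_se[keep] / S_sh[keep]
            w = 1.0 / np.maximum(y_se, 1e-12) ** 2
            X = np.column_stack([shell_q[keep] ** 2, shell_q[keep] ** 4])
            beta = np.linalg.solve(X.T @ (X * w[:, None]), X.T @ (w * y))
            if keep.sum() <= 3 or (n_shell - keep.sum()) >= 2:
                break
            top = np.where(keep)[0][-1]
            y_top = temperature / (A * S_sh[top])
            se_top = y_top * S_shell_se[top] / S_sh[top]
            pred = beta[0] * shell_q[top] ** 2 + beta[1] * shell_q[top] ** 4
            if (pred - y_top) > 2.5 * se_top:
                keep[top] = False
            else:
                break
        return float(beta[1]), float(beta[0]), int(n_shell - keep.sum())

    kappa, sigma_eff, n_trimmed = fit_of(S_shell)

    rng = np.random.default_rng(np.random.PCG64(seed))
    boots = []
    for _ in range(n_bootstrap):
        idx = rng.integers(0, n_blocks, n_blocks)
        boots.append(fit_of(block_shells[idx].mean(axis=0))[0])
    # q^-4 diagnostic: log-log slope over the fitted shells
    slope = float(np.polyfit(np.log(shell_q), np.log(S_shell), 1)[0]) \
        if n_shell >= 3 else np.nan
    return {"kappa": float(kappa),
            "kappa_se": float(np.std(boots)),
            "sigma_eff": sigma_eff,
            "n_trimmed_shells": n_trimmed,
            "spectrum_slope": slope,
            "q4_consistent": bool(abs(slope + 4.0) < 1.5),
            "n_modes": int(sel.sum()),
            "n_frames": len(frames),
            "area": A}


# ---------------------------------------------------------------------------
# stretching modulus
# ---------------------------------------------------------------------------

def integrated_autocorrelation(x: np.ndarray, c: float = 5.0) -> float:
    """Integrated autocorrelation time (in sample units) with Sokal's
    self-consistent window: sum rho(t) while the window < c * tau."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 8:
        return 0.5
    xc = x - x.mean()
    f = np.fft.rfft(xc, 2 * n)
    acf = np.fft.irfft(f * np.conj(f))[:n].real
    if acf[0] <= 0:
        return 0.5
    rho = acf / acf[0] / np.arange(n, 0, -1) * n  # bias-corrected lags
    tau = 0.5
    for t in range(1, n // 2):
        tau += rho[t]
        if t >= c * tau:
            break
    return float(max(tau, 0.5))


def stretching_modulus(areas: np.ndarray, temperature: float = 1.1,
                       n_blocks: int = 10,
                       window_length: int | None = None) -> dict:
    """K_A = k_B T <A> / Var(A) from projected-area fluctuations.

    The sample variance of a window of a correlated series underestimates
    the true variance by a factor ``(1 - 2 tau_int / n)``; the estimate
    is debiased with the measured integrated autocorrelation time.  When
    the series concatenates independent replicas, *window_length* is the
    per-replica sample count and the correction is applied per window
    (pooled around the grand mean, so slow between-replica spread is
    kept).  The blocked standard error comes from contiguous blocks.
    """
    a = np.asarray(areas, dtype=float)
    if len(a) < 4:
        raise AnalysisError("area series too short")
    if a.var() == 0.0:
        raise AnalysisError("zero area variance: was the barostat on?")
    if window_length is None:
        window_length = len(a)
    windows = [a[i:i + window_length]
               for i in range(0, len(a), window_length)]
    grand_mean = float(a.mean())
    vars_corr = []
    taus = []
    for w in windows:
        tau = integrated_autocorrelation(w)
        taus.append(tau)
        # variance about the grand mean keeps between-replica spread
        v = float(((w - grand_mean) ** 2).mean())
        corr = 1.0 - 2.0 * tau / len(w)
        # heavily correlated windows cannot be fully debiased; cap the
        # correction at 2x and report tau so the caller can judge
        vars_corr.append(v / max(corr, 0.5))
    var = float(np.mean(vars_corr))
    ka = temperature * grand_mean / var
    nb = min(n_blocks, len(a) // 4)
    block_vals = []
    for b in np.array_split(a, nb):
        if b.var() > 0:
            block_vals.append(temperature * grand_mean / b.var())
    se = float(np.std(block_vals) / np.sqrt(max(1, len(block_vals))))
    return {"K_A": ka, "K_A_se": se, "mean_area": grand_mean,
            "var_area": var, "n_samples": len(a),
            "tau_int": float(np.mean(taus)),
            "n_windows": len(windows)}


# ---------------------------------------------------------------------------
# synthetic oracles (used by the test suite and documented examples)
# ---------------------------------------------------------------------------

def synthetic_helfrich_frames(kappa: float, L: float, n_cells: int,
                              n_frames: int, temperature: float = 1.1,
                              seed: int = 0, subsample: int = 4,
                              sigma: float = 0.0) -> Trajectory:
    """Trajectory of membrane surfaces sampled from the Helfrich spectrum
    with known *kappa* (synthetic; no dynamics involved).

    Each frame draws independent Gaussian continuum-mode amplitudes with
    ``<|h_q|^2> = k_B T / (A kappa q^4)`` on a grid *subsample* times
    finer than the analysis grid and places one pseudo-bead per fine
    cell, so the standard analysis path -- including its box-filter
    binning and sinc^2 deconvolution -- is exercised end to end.
    """
    rng = np.random.default_rng(np.random.PCG64(seed))
    A = L * L
    nf = n_cells * subsample
    k1 = np.fft.fftfreq(nf) * nf * 2 * np.pi / L
    QX, QY = np.meshgrid(k1, k1, indexing="ij")
    q = np.sqrt(QX**2 + QY**2)
    var = np.zeros_like(q)
    nz = q > 1e-12
    var[nz] = temperature / (A * (sigma * q[nz] ** 2 + kappa * q[nz] ** 4))
    traj = Trajectory()
    cell = L / nf
    xs = (np.arange(nf) + 0.5) * cell
    gx, gy = np.meshgrid(xs, xs, indexing="ij")
    for t in range(n_frames):
        # spectrally filtered white noise: fft2 of a real field is
        # hermitian by construction, and <|fft2(white)_q|^2> = n^2, so
        # scaling by sqrt(var)*n gives <|fft2(h)_q / n^2|^2> = var
        white = rng.standard_normal(q.shape)
        h = np.fft.ifft2(np.fft.fft2(white) * np.sqrt(var)).real * nf
        pos = np.column_stack([gx.ravel(), gy.ravel(), h.ravel()])
        kinds = np.full(len(pos), int(BeadKind.HEAD), dtype=np.int64)
        traj.frames.append(Frame(
            time=float(t), step=t, box=np.array([L, L, 100.0]),
            positions=pos, unwrapped=pos.copy(), kinds=kinds,
            molecule_id=np.zeros(len(pos), dtype=np.int64)))
    return traj
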