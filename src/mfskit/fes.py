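"""Free-energy-surface estimation and basin clustering on a 2-D
collective-variable space (InfleCS-style).

A Gaussian mixture model is fitted to the sampled CV points (model size
selected by BIC over a range of component counts, several seeded restarts
per size); the mixture density on a regular grid gives a free-energy
surface F = -kT ln(rho/rho_max), whose steepest-descent basins define the
conformational clusters and their populations.  The pipeline preset uses
(PC1, extracellular TMH1-TMH7 distance) as the CV pair; the API accepts any
2-D CVs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.mixture import GaussianMixture

logger = logging.getLogger(__name__)

DEFAULT_K_RANGE = range(2, 17)
DEFAULT_GRID = (80, 80)


@dataclass
class DensityModel:
    n_components: int
    weights: np.ndarray
    means: np.ndarray
    covariances: np.ndarray
    log_likelihood: float
    selection_scores: dict[int, float]  # K -> BIC
    _gmm: GaussianMixture = field(repr=False, default=None)

    def density(self, points: np.ndarray) -> np.ndarray:
        return np.exp(self._gmm.score_samples(np.atleast_2d(points)))


def fit_density_model(samples: np.ndarray, k_range=DEFAULT_K_RANGE,
                      n_restarts: int = 5, seed: int = 0) -> DensityModel:
    """EM fit of full-covariance Gaussian mixtures over a range of sizes.

    Each size gets ``n_restarts`` k-means++-seeded initializations; the
    returned model minimizes BIC.  Deterministic given ``seed``.  Degenerate
    covariances are handled by a 1e-6 ridge (logged by scikit-learn)."""
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 2:
        raise ValueError("samples must be (n, d)")
    k_range = list(k_range)
    if len(samples) < 10 * max(k_range):
        warnings.warn(
            f"only {len(samples)} samples for up to {max(k_range)} mixture "
            "components; fits may be unstable", stacklevel=2)
    scores: dict[int, float] = {}
    best = None
    for k in k_range:
        gmm = GaussianMixture(
            n_components=k, covariance_type="full", n_init=n_restarts,
            init_params="k-means++", random_state=seed, reg_covar=1e-6,
            max_iter=500)
        gmm.fit(samples)
        scores[k] = float(gmm.bic(samples))
        if best is None or scores[k] < scores[best.n_components]:
            best = DensityModel(
                n_components=k, weights=gmm.weights_, means=gmm.means_,
                covariances=gmm.covariances_,
                log_likelihood=float(gmm.score(samples) * len(samples)),
                selection_scores={}, _gmm=gmm)
    best.selection_scores = scores
    logger.info("selected K=%d by BIC", best.n_components)
    return best


@dataclass
class FESGrid:
    x_centers: np.ndarray        # (nx,)
    y_centers: np.ndarray        # (ny,)
    free_energy: np.ndarray      # (nx, ny), kT units, min over unmasked = 0
    mask: np.ndarray             # (nx, ny) bool, True = density above floor
    kT: float = 1.0

    @property
    def shape(self):
        return self.free_energy.shape

    def cell_of(self, point) -> tuple[int, int]:
        """Grid cell containing a CV point, clipped to the boundary."""
        i = int(np.clip(np.searchsorted(self.x_centers, point[0]),
                        0, len(self.x_centers) - 1))
        j = int(np.clip(np.searchsorted(self.y_centers, point[1]),
                        0, len(self.y_centers) - 1))
        # snap to nearest center rather than insertion side
        if i > 0 and abs(point[0] - self.x_centers[i - 1]) < abs(point[0] - self.x_centers[i]):
            i -= 1
        if j > 0 and abs(point[1] - self.y_centers[j - 1]) < abs(point[1] - self.y_centers[j]):
            j -= 1
        return i, j


def free_energy_surface(model: DensityModel, cv_ranges,
                        grid_shape=DEFAULT_GRID, kT: float = 1.0,
                        density_floor: float = 1e-6) -> FESGrid:
    """F(cell) = -kT ln(rho(cell)/rho_max) on a regular grid of cell
    centers; cells below ``density_floor * rho_max`` are masked."""
    (x0, x1), (y0, y1) = cv_ranges
    nx, ny = grid_shape
    xc = x0 + (np.arange(nx) + 0.5) * (x1 - x0) / nx
    yc = y0 + (np.arange(ny) + 0.5) * (y1 - y0) / ny
    gx, gy = np.meshgrid(xc, yc, indexing="ij")
    rho = model.density(np.column_stack([gx.ravel(), gy.ravel()])).reshape(nx, ny)
    rho_max = rho.max()
    mask = rho >= density_floor * rho_max
    with np.errstate(divide="ignore"):
        fe = -kT * np.log(rho / rho_max)
    return FESGrid(x_centers=xc, y_centers=yc, free_energy=fe, mask=mask, kT=kT)


@dataclass
class BasinPartition:
    labels: np.ndarray   # (nx, ny) int, -1 on masked cells
    minima: dict[int, tuple[int, int]]  # basin label -> minimum cell

    @property
    def n_basins(self) -> int:
        return len(self.minima)


_NEIGHBORS = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1)
              if (di, dj) != (0, 0)]


def extract_basins(grid: FESGrid, merge_radius: int = 1) -> BasinPartition:
    """Steepest-descent basins on the 8-connected grid.

    Every unmasked cell descends to its lowest neighbor until a local
    minimum; basins are the descent equivalence classes.  Minima within
    ``merge_radius`` cells (Chebyshev) of each other are merged."""
    nx, ny = grid.shape
    fe = np.where(grid.mask, grid.free_energy, np.inf)
    downhill = -np.ones((nx, ny, 2), dtype=int)
    for i in range(nx):
        for j in range(ny):
            if not grid.mask[i, j]:
                continue
            best = (i, j)
            best_f = fe[i, j]
            for di, dj in _NEIGHBORS:
                ii, jj = i + di, j + dj
                if 0 <= ii < nx and 0 <= jj < ny and fe[ii, jj] < best_f:
                    best_f = fe[ii, jj]
                    best = (ii, jj)
            downhill[i, j] = best
    # memoized pointer chasing to each cell's terminal minimum
    terminal: dict[tuple[int, int], tuple[int, int]] = {}

    def descend(cell):
        path = []
        while cell not in terminal:
            nxt = tuple(downhill[cell[0], cell[1]])
            if nxt == cell:
                terminal[cell] = cell
                break
            path.append(cell)
            cell = nxt
        root = terminal[cell]
        for c in path:
            terminal[c] = root
        return root

    minima: list[tuple[int, int]] = []
    labels = -np.ones((nx, ny), dtype=int)
    cell_min: dict[tuple[int, int], int] = {}
    for i in range(nx):
        for j in range(ny):
            if not grid.mask[i, j]:
                continue
            m = descend((i, j))
            if m not in cell_min:
                cell_min[m] = len(minima)
                minima.append(m)
    # merge minima closer than merge_radius cells (union-find)
    parent = list(range(len(minima)))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for a in range(len(minima)):
        for b in range(a + 1, len(minima)):
            da = abs(minima[a][0] - minima[b][0])
            db = abs(minima[a][1] - minima[b][1])
            if max(da, db) <= merge_radius:
                parent[find(b)] = find(a)
    # relabel merged roots contiguously, keeping the deepest minimum
    root_label: dict[int, int] = {}
    root_min: dict[int, tuple[int, int]] = {}
    for idx, m in enumerate(minima):
        r = find(idx)
        if r not in root_label:
            root_label[r] = len(root_label)
            root_min[r] = m
        elif fe[m] < fe[root_min[r]]:
            root_min[r] = m
    for i in range(nx):
        for j in range(ny):
            if grid.mask[i, j]:
                labels[i, j] = root_label[find(cell_min[descend((i, j))])]
    final_minima = {root_label[r]: m for r, m in root_min.items()}
    return BasinPartition(labels=labels, minima=final_minima)


@dataclass
class BasinAssignment:
    sample_labels: np.ndarray           # (n,)
    populations: dict[int, float]       # basin -> fraction of samples
    representatives: dict[int, tuple[int, int]]  # basin -> minimum cell
    n_out_of_range: int = 0


def assign_clusters_and_populations(samples: np.ndarray, grid: FESGrid,
                                    basins: BasinPartition) -> BasinAssignment:
    """Map samples to their cell's basin; populations are label
    frequencies.  Samples outside the CV ranges are clipped to the nearest
    boundary cell and counted in ``n_out_of_range``; samples landing on a
    masked cell take the nearest unmasked cell's basin."""
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    unmasked = np.argwhere(basins.labels >= 0)
    labels = np.empty(len(samples), dtype=int)
    x0, x1 = grid.x_centers[0], grid.x_centers[-1]
    y0, y1 = grid.y_centers[0], grid.y_centers[-1]
    out = 0
    for n, p in enumerate(samples):
        if not (x0 <= p[0] <= x1 and y0 <= p[1] <= y1):
            out += 1
        i, j = grid.cell_of(p)
        lab = basins.labels[i, j]
        if lab < 0:
            d2 = (unmasked[:, 0] - i) ** 2 + (unmasked[:, 1] - j) ** 2
            ii, jj = unmasked[np.argmin(d2)]
            lab = basins.labels[ii, jj]
        labels[n] = lab
    uniq, counts = np.unique(labels, return_counts=True)
    pops = {int(u): float(c) / len(samples) for u, c in zip(uniq, counts)}
    return BasinAssignment(
        sample_labels=labels, populations=pops,
        representatives={int(u): basins.minima[int(u)] for u in uniq},
        n_out_of_range=out)


def write_fes_grid(grid: FESGrid, path: str) -> None:
    """Plain-text matrix with a metadata header."""
    with open(path, "w") as fh:
        fh.write(f"# kT {grid.kT}\n")
        fh.write("# x_centers " + " ".join(f"{x:.6g}" for x in grid.x_centers) + "\n")
        fh.write("# y_centers " + " ".join(f"{y:.6g}" for y in grid.y_centers) + "\n")
        for row in grid.free_energy:
            fh.write(" ".join("inf" if not np.isfinite(v) else f"{v:.6f}"
                              for v in row) + "\n")
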