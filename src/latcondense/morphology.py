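"""Classification of condensate patterns into the observed morphology classes.

Final density fields from the phase-field solver (or from experiments, in
principle) fall into six classes: still homogeneous, bicontinuous (both
phases percolate), or a minority phase of LAT-rich / LAT-depleted inclusions
that are droplet-like circular or elongated non-circular.

The classifier binarizes the field with an Otsu threshold, labels connected
components with full periodic (torus) adjacency, detects percolation by
winding (a component that connects to a shifted copy of itself across the
period), and separates circular from elongated inclusions by the shape
factor 4*pi*A/P^2 with a Cauchy-Crofton perimeter estimate evaluated
periodically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label as _cc_label

__all__ = [
    "MORPHOLOGY_LABELS",
    "ComponentStats",
    "detect_separation",
    "binarize_phases",
    "periodic_components",
    "classify",
    "phase_diagram",
    "fixture_fields",
]

MORPHOLOGY_LABELS = (
    "homogeneous",
    "bicontinuous",
    "rich_circular",
    "rich_noncircular",
    "depleted_circular",
    "depleted_noncircular",
)

# classifier decision constants (configurable via classify(...) keywords)
# Otsu class-mean gap, in units of the reference density: stationary
# separated states with a shallow favored well can have inter-phase contrast
# as low as ~0.17 of the reference density, while unseparated noise sits
# orders of magnitude below this cut
BIMODALITY_GAP_FRAC = 0.1
CIRCULARITY_CUT = 0.75
MIN_COMPONENT_CELLS = 10


@dataclass
class ComponentStats:
    """Geometry of one periodic connected component of a binary phase mask."""

    area: float  # grid cells x cell area
    perimeter: float  # Crofton estimate, same length unit as sqrt(cell area)
    circularity: float  # 4*pi*A/P^2, 1 for a disk
    wraps_x: bool  # winds around the second (column) axis
    wraps_y: bool  # winds around the first (row) axis

    @property
    def spanning(self) -> bool:
        return self.wraps_x or self.wraps_y


def detect_separation(L: np.ndarray, L0: float | None = None) -> bool:
    """Bimodality test: Otsu class means separated by a fraction of the
    reference density (BIMODALITY_GAP_FRAC).

    Noise-level variance around a single mode yields a small class-mean gap
    and returns False; a separated field has modes ~O(1) apart in these
    units (reference density defaults to the field mean).
    """
    L = np.asarray(L, dtype=float)
    if not np.all(np.isfinite(L)):
        raise ValueError("field contains non-finite values")
    ref = float(L.mean()) if L0 is None else float(L0)
    if L.max() - L.min() < 1e-12 * max(1.0, abs(ref)):
        return False
    thr = threshold_otsu(L)
    lo, hi = L[L <= thr], L[L > thr]
    if lo.size == 0 or hi.size == 0:
        return False
    return float(hi.mean() - lo.mean()) > BIMODALITY_GAP_FRAC * ref


def binarize_phases(L: np.ndarray) -> np.ndarray:
    """Otsu-threshold mask of the dense (LAT-rich) phase.

    Callers must gate on :func:`detect_separation`; a degenerate unimodal
    field raises.
    """
    L = np.asarray(L, dtype=float)
    if L.max() - L.min() < 1e-12:
        raise ValueError("cannot binarize a (near-)constant field")
    return L > threshold_otsu(L)


class _SeamUnionFind:
    """Union-find over non-periodic sublabels with 2-D lift potentials.

    Each sublabel carries the lift (universal-cover offset) of its pixels
    relative to its root.  A seam edge whose implied lift disagrees with the
    stored one by a period multiple reveals that the merged component winds
    around that direction.
    """

    def __init__(self, n_labels: int):
        self.parent = list(range(n_labels + 1))
        self.off = [(0, 0)] * (n_labels + 1)  # offset of label w.r.t. parent
        self.windy = [False] * (n_labels + 1)  # winds around axis 0
        self.windx = [False] * (n_labels + 1)  # winds around axis 1

    def find(self, a):
        path = []
        while self.parent[a] != a:
            path.append(a)
            a = self.parent[a]
        oy = ox = 0
        for b in reversed(path):
            oy += self.off[b][0]
            ox += self.off[b][1]
            self.parent[b] = a
            self.off[b] = (oy, ox)
        return a, self.off[path[0]] if path else (0, 0)

    def union(self, a, b, delta):
        """Impose lift(b) - lift(a) = delta for one seam adjacency."""
        ra, offa = self.find(a)
        rb, offb = self.find(b)
        if ra == rb:
            dy = offb[0] - offa[0] - delta[0]
            dx = offb[1] - offa[1] - delta[1]
            if dy:
                self.windy[ra] = True
            if dx:
                self.windx[ra] = True
        else:
            # attach rb under ra: off[rb] = lift(b under ra) - current zero
            self.parent[rb] = ra
            self.off[rb] = (offa[0] + delta[0] - offb[0], offa[1] + delta[1] - offb[1])
            self.windy[ra] = self.windy[ra] or self.windy[rb]
            self.windx[ra] = self.windx[ra] or self.windx[rb]


def _periodic_label(mask: np.ndarray, connectivity: int = 2):
    """Torus connected-component labels plus per-label winding flags.

    Returns (labels, wraps_x, wraps_y) where the dicts map each compressed
    label to its percolation flags (wraps_y: winds along axis 0).
    """
    lab = _cc_label(mask, connectivity=connectivity)
    nlab = int(lab.max())
    if nlab == 0:
        return lab, {}, {}
    n0, n1 = mask.shape
    uf = _SeamUnionFind(nlab)
    shifts = [0] if connectivity == 1 else [-1, 0, 1]
    # seam between last and first column: pixel (i, n1-1) ~ (i+di, 0), the
    # neighbour's lift sits one column to the right of column n1-1
    for di in shifts:
        a = lab[:, -1]
        b = np.roll(lab[:, 0], -di)
        rows = np.nonzero((a > 0) & (b > 0))[0]
        for i in rows:
            ib = (i + di) % n0
            # lift(b) - lift(a) = (i + di - ib, n1 - 0 - 0) relative to
            # stored coords (ib, 0) vs (i, n1-1): delta = (i+di-ib, n1)
            uf.union(int(a[i]), int(b[i]), (i + di - ib, n1))
    # seam between last and first row
    for di in shifts:
        a = lab[-1, :]
        b = np.roll(lab[0, :], -di)
        cols = np.nonzero((a > 0) & (b > 0))[0]
        for j in cols:
            jb = (j + di) % n1
            uf.union(int(a[j]), int(b[j]), (n0, j + di - jb))
    roots = np.empty(nlab + 1, dtype=int)
    for k in range(nlab + 1):
        roots[k], _ = uf.find(k) if k else (0, None)
    uniq = np.unique(roots[1:])
    remap = np.zeros(nlab + 1, dtype=int)
    remap[uniq] = np.arange(1, uniq.size + 1)
    wraps_x = {int(remap[r]): uf.windx[r] for r in uniq}
    wraps_y = {int(remap[r]): uf.windy[r] for r in uniq}
    return remap[roots[lab]], wraps_x, wraps_y


def _crofton_perimeter(comp: np.ndarray) -> float:
    """Cauchy-Crofton perimeter of a binary set on the torus, in cell units.

    P = (pi/2) * mean over 4 line directions of (crossing count x spacing);
    crossings are neighbor sign changes evaluated with periodic rolls, so
    components crossing or winding the boundary need no special casing.
    """
    c0 = np.sum(comp != np.roll(comp, 1, axis=0))
    c1 = np.sum(comp != np.roll(comp, 1, axis=1))
    cd1 = np.sum(comp != np.roll(comp, (1, 1), axis=(0, 1)))
    cd2 = np.sum(comp != np.roll(comp, (1, -1), axis=(0, 1)))
    s_ax, s_diag = 1.0, 1.0 / np.sqrt(2.0)
    return float(np.pi / 2.0 * (c0 * s_ax + c1 * s_ax + (cd1 + cd2) * s_diag) / 4.0)


def periodic_components(
    mask: np.ndarray, connectivity: int = 2, cell_area: float = 1.0
) -> list[ComponentStats]:
    """Per-component geometry of a binary mask with periodic adjacency."""
    mask = np.asarray(mask, dtype=bool)
    lab, wraps_x, wraps_y = _periodic_label(mask, connectivity=connectivity)
    stats = []
    cell = np.sqrt(cell_area)
    for k in range(1, lab.max() + 1):
        comp = lab == k
        area_cells = int(comp.sum())
        per = _crofton_perimeter(comp)
        circ = 4.0 * np.pi * area_cells / per**2 if per > 0 else 1.0
        stats.append(
            ComponentStats(
                area=area_cells * cell_area,
                perimeter=per * cell,
                circularity=float(circ),
                wraps_x=wraps_x[k],
                wraps_y=wraps_y[k],
            )
        )
    return stats


def _area_weighted_median_circularity(comps: list[ComponentStats]) -> float:
    comps = sorted(comps, key=lambda c: c.circularity)
    total = sum(c.area for c in comps)
    acc = 0.0
    for c in comps:
        acc += c.area
        if acc >= 0.5 * total:
            return c.circularity
    return comps[-1].circularity if comps else 1.0


def classify(
    L: np.ndarray,
    p=None,
    *,
    L0: float | None = None,
    circularity_cut: float = CIRCULARITY_CUT,
    min_cells: int = MIN_COMPONENT_CELLS,
) -> str:
    """Assign one of the six morphology labels to a density field.

    homogeneous if no bimodal separation; bicontinuous if both phases own a
    periodically spanning component; otherwise the minority phase (smaller
    area fraction) names the label (rich_* / depleted_*), with circular vs
    noncircular decided by the area-weighted median circularity of minority
    components larger than ``min_cells`` grid cells.
    """
    L = np.asarray(L, dtype=float)
    ref = L0
    if ref is None and p is not None:
        ref = getattr(p, "L_bar", None)
    if not detect_separation(L, ref):
        return "homogeneous"
    rich = binarize_phases(L)
    comps_rich = periodic_components(rich)
    comps_dep = periodic_components(~rich)
    rich_spans = any(c.spanning for c in comps_rich)
    dep_spans = any(c.spanning for c in comps_dep)
    if rich_spans and dep_spans:
        return "bicontinuous"
    rich_frac = rich.mean()
    minority_is_rich = rich_frac <= 0.5
    comps = comps_rich if minority_is_rich else comps_dep
    big = [c for c in comps if c.area >= min_cells]
    if not big:
        big = comps
    med_circ = _area_weighted_median_circularity(big)
    shape = "circular" if med_circ > circularity_cut else "noncircular"
    return f"{'rich' if minority_is_rich else 'depleted'}_{shape}"


def phase_diagram(
    scan,
    p_base,
    g,
    cfg,
    base_seed: int = 0,
) -> "pandas.DataFrame":
    """Run and classify a (beta3_hat, beta4_hat) scan of the field model.

    Each admissible point gets an independent, deterministic seed
    (base_seed XOR point index); inadmissible points are flagged and
    skipped, and individual run failures are recorded as "failed".
    Returns a table (beta3_hat, beta4_hat, admissible, label).
    """
    import pandas as pd

    from .field_dynamics import admissible as _adm
    from .field_dynamics import run_simulation

    rows = []
    for idx, (b3, b4) in enumerate(scan):
        ok = _adm(b3, b4, p_base.phi_th, p_base.v)
        row = {"beta3_hat": b3, "beta4_hat": b4, "admissible": ok, "label": "skipped"}
        if ok:
            p = p_base.with_(beta3_hat=b3, beta4_hat=b4)
            c = cfg.with_(seed=(base_seed ^ idx) & 0x7FFFFFFF)
            try:
                snaps, _ = run_simulation(p, g, c)
                row["label"] = classify(snaps[-1].L, p)
            except (FloatingPointError, RuntimeError):
                row["label"] = "failed"
        rows.append(row)
    return pd.DataFrame(rows)


def fixture_fields(
    n: int = 128, L_bar: float = 3.0, contrast: float = 1.0, seed: int = 0
) -> dict:
    """Synthetic labeled density fields, one per morphology class.

    Ground-truth patterns for classifier tests and demos: uniform noise
    (homogeneous), disks on a low background (rich_circular) and their
    inversion (depleted_circular), elongated 4:1 bars (rich_/
    depleted_noncircular), and stripes (bicontinuous).  ``contrast`` is the
    density difference between the two phases.
    """
    rng = np.random.default_rng(seed)
    lo, hi = L_bar - 0.5 * contrast, L_bar + 0.5 * contrast
    noise = 1e-3 * L_bar * rng.standard_normal((n, n))
    ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")

    def disks(centers, radius):
        m = np.zeros((n, n), dtype=bool)
        for ci, cj in centers:
            di = (ii - ci + n / 2) % n - n / 2
            dj = (jj - cj + n / 2) % n - n / 2
            m |= di**2 + dj**2 <= radius**2
        return m

    def bars(centers, half_len, half_wid):
        m = np.zeros((n, n), dtype=bool)
        for ci, cj in centers:
            di = np.abs((ii - ci + n / 2) % n - n / 2)
            dj = np.abs((jj - cj + n / 2) % n - n / 2)
            m |= (di <= half_wid) & (dj <= half_len)
        return m

    r = n // 10
    disk_centers = [(n // 4, n // 4), (n // 4, 3 * n // 4), (3 * n // 4, n // 2)]
    bar_centers = [(n // 4, n // 4), (5 * n // 8, 5 * n // 8)]
    disk_mask = disks(disk_centers, r)
    bar_mask = bars(bar_centers, half_len=n // 5, half_wid=n // 20)
    stripe_mask = (ii // (n // 8)) % 2 == 0

    def field(mask):
        return np.where(mask, hi, lo) + noise

    return {
        "homogeneous": np.full((n, n), L_bar) + noise,
        "rich_circular": field(disk_mask),
        "depleted_circular": field(~disk_mask),
        "rich_noncircular": field(bar_mask),
        "depleted_noncircular": field(~bar_mask),
        "bicontinuous": field(stripe_mask),
    }
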