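"""Synthetic boundary shapes and synthetic cohorts.

Everything the pipeline consumes can be generated here with known ground
truth: masks whose medial edge is an analytic curve (with closed-form
descriptor values where they exist), cohorts whose covariate frequencies
match the study's published marginal tables, and progression-free-survival
times drawn from a proportional-hazards model whose coefficients are the
published risk-score weights — so parameter-recovery and calibration tests
have an exact generating truth.

All generators are fully seeded: same spec + same seed gives bit-identical
output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import fresnel

from .errors import GlioshapeError
from .geometry import BoundaryCurve, MaskSlice

__all__ = [
    "ShapeSpec",
    "CohortSpec",
    "make_shape",
    "make_cohort",
    "make_reference_cohort",
    "make_survival_fixture",
    "KOCH_FD",
]

#: similarity dimension of the Koch curve, log 4 / log 3
KOCH_FD = math.log(4) / math.log(3)


# --------------------------------------------------------------------------
# shapes
# --------------------------------------------------------------------------

@dataclass
class ShapeSpec:
    """Parameters of one synthetic boundary shape.

    family is one of ``straight-edge``, ``arc``, ``sinusoid``, ``koch``,
    ``clothoid``.  ``radius`` (mm) and ``angle`` (degrees) apply to arcs;
    ``amplitude``/``wavelength`` (mm) to sinusoids; ``iterations`` to the
    Koch curve; ``curvature_rate`` (1/mm², the constant dκ/ds) and
    ``arc_limit`` (total turning in radians) to clothoids.  ``jitter``
    adds iid Gaussian noise (sd in mm) to the returned ground-truth curve,
    emulating tracing error; the mask itself is noise-free.
    """

    family: str = "arc"
    radius: float = 20.0
    angle: float = 180.0
    amplitude: float = 3.0
    wavelength: float = 20.0
    iterations: int = 4
    curvature_rate: float = 0.02
    arc_limit: float = 2.0
    size: float = 60.0           # characteristic extent, mm
    raster_shape: tuple[int, int] = (256, 256)
    spacing: tuple[float, float] = (0.5, 0.5)
    jitter: float = 0.0
    n_points: int = 1001
    seed: int = 0


def _raster_from_region(inside_fn, spec: ShapeSpec) -> MaskSlice:
    """Sample a region indicator at pixel centers (no anti-aliasing)."""
    h, w = spec.raster_shape
    sr, sc = spec.spacing
    rows, cols = np.mgrid[0:h, 0:w]
    x = cols * sc
    y = rows * sr
    pix = inside_fn(x, y)
    if not pix.any():
        raise GlioshapeError("shape-outside-raster", "shape misses the raster")
    if pix.all():
        raise GlioshapeError("shape-outside-raster", "shape fills the raster")
    return MaskSlice(pix, spacing=spec.spacing)


def _koch_polyline(iterations: int, size: float) -> np.ndarray:
    pts = np.array([[0.0, 0.0], [size, 0.0]])
    for _ in range(iterations):
        out = [pts[0]]
        for a, b in zip(pts[:-1], pts[1:]):
            d = (b - a) / 3.0
            p1 = a + d
            p2 = a + 2 * d
            # apex of the equilateral bump, on the +y side
            mid = (p1 + p2) / 2.0
            normal = np.array([-d[1], d[0]])
            apex = mid + normal * math.sqrt(3) / 2.0
            out.extend([p1, apex, p2])
            out.append(b)
        pts = np.array(out)
    return pts


def make_shape(spec: ShapeSpec) -> tuple[MaskSlice, BoundaryCurve, dict]:
    """Rasterized mask, exact medial polyline, and analytic descriptors.

    The analytic dict carries only the values that exist in closed form for
    the family: ``tortuosity``, ``total_curvature``, ``max_curvature``,
    ``average_curvature``, ``curvature_variation``, ``fd``.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.raster_shape
    sr, sc = spec.spacing
    cx, cy = (w - 1) * sc / 2.0, (h - 1) * sr / 2.0
    analytic: dict[str, float] = {}

    if spec.family == "straight-edge":
        x_edge = cx + spec.size / 4.0
        mask = _raster_from_region(lambda x, y: x <= x_edge, spec)
        # the medial edge spans the whole raster height
        ys = np.linspace(0.0, (h - 1) * sr, spec.n_points)
        curve_pts = np.column_stack([np.full_like(ys, x_edge), ys])
        mask.medial_hint = (1.0, 0.0)
        analytic.update(tortuosity=1.0, total_curvature=0.0, max_curvature=0.0,
                        average_curvature=0.0, curvature_variation=0.0)
    elif spec.family == "arc":
        r = spec.radius
        mask = _raster_from_region(
            lambda x, y: (x - cx) ** 2 + (y - cy) ** 2 <= r ** 2, spec)
        half = math.radians(spec.angle) / 2.0
        th = np.linspace(-half, half, spec.n_points)
        curve_pts = np.column_stack([cx + r * np.cos(th), cy + r * np.sin(th)])
        mask.medial_hint = (1.0, 0.0)
        theta = math.radians(spec.angle)
        analytic.update(
            tortuosity=(theta / 2.0) / math.sin(theta / 2.0),
            total_curvature=theta,
            max_curvature=1.0 / r,
            average_curvature=1.0 / r,
            curvature_variation=0.0,
        )
    elif spec.family == "sinusoid":
        a, lam = spec.amplitude, spec.wavelength
        x0 = cx + spec.size / 4.0
        mask = _raster_from_region(
            lambda x, y: x <= x0 + a * np.sin(2 * np.pi * y / lam), spec)
        ys = np.linspace(0.0, (h - 1) * sr, spec.n_points)
        xs = x0 + a * np.sin(2 * np.pi * ys / lam)
        curve_pts = np.column_stack([xs, ys])
        mask.medial_hint = (1.0, 0.0)
    elif spec.family == "koch":
        curve_pts = _koch_polyline(spec.iterations, spec.size)
        # center on the raster; close the polygon along the baseline side
        offset = np.array([cx - spec.size / 2.0, cy])
        curve_pts = curve_pts + offset
        from skimage.draw import polygon

        poly = np.vstack([curve_pts,
                          curve_pts[-1] + [0, -spec.size / 4.0],
                          curve_pts[0] + [0, -spec.size / 4.0]])
        rr, cc = polygon(poly[:, 1] / sr, poly[:, 0] / sc, shape=(h, w))
        pix = np.zeros((h, w), dtype=bool)
        pix[rr, cc] = True
        mask = MaskSlice(pix, spacing=spec.spacing, medial_hint=(0.0, 1.0))
        analytic.update(fd=KOCH_FD, tortuosity=(4.0 / 3.0) ** spec.iterations)
    elif spec.family == "clothoid":
        c = spec.curvature_rate
        s_max = math.sqrt(2.0 * spec.arc_limit / c)
        s = np.linspace(0.0, s_max, spec.n_points)
        scale = math.sqrt(math.pi / c)
        ss, cc_ = fresnel(s / scale)
        curve_pts = np.column_stack([cc_ * scale, ss * scale])
        curve_pts += np.array([cx - curve_pts[:, 0].mean(),
                               cy - curve_pts[:, 1].mean()])
        from skimage.draw import polygon

        poly = np.vstack([curve_pts, curve_pts[-1] + [0, -spec.size / 2.0],
                          curve_pts[0] + [0, -spec.size / 2.0]])
        rr, ccx = polygon(poly[:, 1] / sr, poly[:, 0] / sc, shape=(h, w))
        pix = np.zeros((h, w), dtype=bool)
        pix[rr, ccx] = True
        mask = MaskSlice(pix, spacing=spec.spacing, medial_hint=(0.0, 1.0))
        analytic.update(curvature_variation=c,
                        max_curvature=c * s_max,
                        average_curvature=c * s_max / 2.0,
                        total_curvature=c * s_max ** 2 / 2.0)
    else:
        raise GlioshapeError("unknown-family", f"unknown shape family {spec.family!r}")

    if spec.jitter > 0:
        curve_pts = curve_pts + rng.normal(0.0, spec.jitter, curve_pts.shape)
    return mask, BoundaryCurve(curve_pts), analytic


# --------------------------------------------------------------------------
# cohorts
# --------------------------------------------------------------------------

# Published marginal 2x2 counts per variable: level -> (n_linear, n_curved).
# Subtotals below the shape totals (161 L / 169 C) encode per-variable
# missingness, reproduced as empty cells.
PUBLISHED_MARGINS: dict[str, dict] = {
    "age": {"levels": ["<=38", ">38"], "L": [91, 70], "C": [58, 111],
            "printed_or": 0.40, "printed_ci": (0.26, 0.63), "printed_p": "<0.001",
            "orientation": "row2-first", "consistent": True},
    "gender": {"levels": ["male", "female"], "L": [85, 76], "C": [92, 77],
               "printed_or": 0.94, "printed_ci": (0.60, 1.45), "printed_p": "0.83",
               "orientation": "row1-first", "consistent": True},
    "side": {"levels": ["left", "right"], "L": [78, 83], "C": [89, 80],
             "printed_or": 0.84, "printed_ci": (0.54, 1.30), "printed_p": "0.51",
             "orientation": "row1-first", "consistent": True},
    "volume": {"levels": ["<=20.17", ">20.17"], "L": [22, 139], "C": [12, 157],
               "printed_or": 2.07, "printed_ci": (0.98, 4.27), "printed_p": "0.07",
               "orientation": "row1-first", "consistent": True},
    "histology": {"levels": ["OGS", "non-OGS"], "L": [46, 74], "C": [71, 65],
                  "printed_or": 0.57, "printed_ci": (0.35, 0.95), "printed_p": "0.03",
                  "orientation": "row1-first", "consistent": True},
    "who_grade": {"levels": ["2", "3"], "L": [108, 53], "C": [117, 52],
                  "printed_or": 0.91, "printed_ci": (0.58, 1.43), "printed_p": "0.72",
                  "orientation": "row1-first", "consistent": True},
    "idh1": {"levels": ["mutant", "wild"], "L": [73, 14], "C": [85, 15],
             "printed_or": 0.92, "printed_ci": (0.44, 1.98), "printed_p": "0.84",
             "orientation": "row1-first", "consistent": True},
    "chr1p19q": {"levels": ["co-deleted", "intact"], "L": [31, 72], "C": [49, 63],
                 "printed_or": 0.55, "printed_ci": (0.32, 0.97), "printed_p": "0.05",
                 "orientation": "row1-first", "consistent": True},
    "idh1_with_1p19q": {"levels": ["with", "without"], "L": [9, 34], "C": [44, 65],
                        "printed_or": 0.39, "printed_ci": (0.16, 0.87),
                        "printed_p": "0.02",
                        "orientation": "row1-first", "consistent": True},
    "atrx": {"levels": ["mutant", "wild"], "L": [59, 43], "C": [49, 63],
             "printed_or": 0.57, "printed_ci": (0.33, 0.96), "printed_p": "0.04",
             "orientation": "row2-first", "consistent": True},
    "mgmt": {"levels": ["methylated", "unmethylated"], "L": [52, 17], "C": [53, 14],
             "printed_or": 0.81, "printed_ci": (0.37, 1.76), "printed_p": "0.68",
             "orientation": "row1-first", "consistent": True},
    "tp53": {"levels": ["mutant", "wild"], "L": [71, 58], "C": [58, 88],
             "printed_or": 0.54, "printed_ci": (0.33, 0.86), "printed_p": "0.02",
             "orientation": "row2-first", "consistent": True},
    "ki67": {"levels": ["<=10%", ">10%"], "L": [38, 70], "C": [64, 67],
             "printed_or": 0.57, "printed_ci": (0.34, 0.96), "printed_p": "0.04",
             "orientation": "row1-first", "consistent": True},
    # printed OR 1.21 is not reproducible from the printed counts under
    # either row orientation (cross-products 1.12 / 0.89); kept for
    # completeness but excluded from the reproduction suite.
    "epilepsy": {"levels": ["yes", "no"], "L": [95, 66], "C": [95, 74],
                 "printed_or": 1.21, "printed_ci": (0.72, 1.72), "printed_p": "0.66",
                 "orientation": "row1-first", "consistent": False},
}

N_LINEAR, N_CURVED = 161, 169

#: published risk-score weights, used here as the generating truth
RISK_L_COEFFS = {"ki67_high": 0.78, "epilepsy_yes": 0.54, "tp53_mutant": -0.77,
                 "chr1p19q_codel": -0.90, "volume_high": 0.55}
RISK_C_COEFFS = {"ki67_high": 0.04, "idh1_mutant": -0.86, "age_high": 1.31,
                 "volume_high": 1.39, "tortuosity_high": 1.19,
                 "chr1p19q_codel": -1.70}


@dataclass
class CohortSpec:
    """Conditions for one synthetic cohort.

    Covariates are drawn independently given the shape label, with
    conditional level frequencies defaulting to the published marginal
    tables.  PFS is exponential with hazard
    ``baseline_hazard * exp(linear predictor)`` where the linear predictor
    uses ``risk_coeffs`` on the binary-coded adverse indicators; censoring
    is uniform over (0, ``followup_months``].
    """

    n: int = 330
    p_curved: float = N_CURVED / (N_LINEAR + N_CURVED)
    baseline_hazard: float = 0.012        # events per month at indicator 0
    risk_coeffs: dict[str, float] = field(
        default_factory=lambda: dict(RISK_L_COEFFS))
    followup_months: float = 180.0
    include_missing: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise GlioshapeError("bad-spec", "n must be >= 1")
        if not (0 <= self.p_curved <= 1):
            raise GlioshapeError("bad-spec", "p_curved must be a probability")
        if self.baseline_hazard <= 0:
            raise GlioshapeError("bad-spec", "baseline hazard must be > 0")


# continuous ranges used to realize a value on either side of a cut-point
_CONT_RANGES = {
    "age": (18.0, 38.0, 75.0),
    "volume": (3.0, 20.17, 110.0),
    "ki67_index": (0.01, 0.10, 0.60),
    "tortuosity": (1.0, 1.15, 2.2),
}


def _cond_p(var: str, shape: str) -> float:
    """P(level 1 | shape) from the marginal table."""
    row = PUBLISHED_MARGINS[var]
    counts = row["L"] if shape == "L" else row["C"]
    return counts[0] / sum(counts)


def _obs_p(var: str, shape: str) -> float:
    """P(observed | shape): subtotal over the shape-group size."""
    row = PUBLISHED_MARGINS[var]
    total = N_LINEAR if shape == "L" else N_CURVED
    return min(sum(row["L"] if shape == "L" else row["C"]) / total, 1.0)


def _draw_continuous(rng, var: str, low_side: np.ndarray) -> np.ndarray:
    lo, cut, hi = _CONT_RANGES[var]
    low = rng.uniform(lo, cut, low_side.shape)
    high = rng.uniform(np.nextafter(cut, hi), hi, low_side.shape)
    return np.where(low_side, low, high)


def make_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a synthetic cohort table.

    Columns: id, age, gender, side, volume, histology, who_grade, idh1,
    chr1p19q, atrx, mgmt, tp53, ki67_index, epilepsy, tortuosity,
    shape_label, pfs_months, event.  Categorical levels are strings; missing
    marker calls are NaN.  PFS truth is generated before missingness is
    applied, so complete-case refits remain unbiased for the generating
    coefficients.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    shape = np.where(rng.random(n) < spec.p_curved, "C", "L")

    def cond(var):
        p = np.where(shape == "C", _cond_p(var, "C"), _cond_p(var, "L"))
        return rng.random(n) < p

    df = pd.DataFrame({"id": [f"P{i:05d}" for i in range(n)]})
    df["shape_label"] = shape
    age_low = cond("age")
    df["age"] = _draw_continuous(rng, "age", age_low)
    df["gender"] = np.where(cond("gender"), "male", "female")
    df["side"] = np.where(cond("side"), "left", "right")
    vol_low = cond("volume")
    df["volume"] = _draw_continuous(rng, "volume", vol_low)
    df["histology"] = np.where(cond("histology"), "OGS", "non-OGS")
    df["who_grade"] = np.where(cond("who_grade"), "2", "3")
    idh1 = np.where(cond("idh1"), "mutant", "wild")
    codel = np.where(cond("chr1p19q"), "co-deleted", "intact")
    atrx = np.where(cond("atrx"), "mutant", "wild")
    mgmt = np.where(cond("mgmt"), "methylated", "unmethylated")
    tp53 = np.where(cond("tp53"), "mutant", "wild")
    ki_low = cond("ki67")
    ki67 = _draw_continuous(rng, "ki67_index", ki_low)
    df["epilepsy"] = np.where(cond("epilepsy"), "yes", "no")
    # tortuosity: measured on the medial arc; higher for curved boundaries
    tort = np.where(shape == "C",
                    rng.uniform(1.05, 2.2, n), rng.uniform(1.0, 1.25, n))

    # survival from the generating risk model (pre-missingness truth)
    indicators = {
        "ki67_high": (ki67 > 0.10).astype(float),
        "epilepsy_yes": (df["epilepsy"] == "yes").to_numpy(float),
        "tp53_mutant": (tp53 == "mutant").astype(float),
        "chr1p19q_codel": (codel == "co-deleted").astype(float),
        "volume_high": (df["volume"] > 20.17).to_numpy(float),
        "idh1_mutant": (idh1 == "mutant").astype(float),
        "age_high": (df["age"] > 38).to_numpy(float),
        "tortuosity_high": (tort > np.median(tort)).astype(float),
    }
    lp = np.zeros(n)
    for name, beta in spec.risk_coeffs.items():
        if name not in indicators:
            raise GlioshapeError("bad-spec", f"unknown risk covariate {name!r}")
        lp += beta * indicators[name]
    hazard = spec.baseline_hazard * np.exp(lp)
    event_time = rng.exponential(1.0 / hazard)
    censor_time = rng.uniform(0.0, spec.followup_months, n)
    df["pfs_months"] = np.minimum(event_time, censor_time)
    df["event"] = (event_time <= censor_time).astype(int)

    df["idh1"], df["chr1p19q"], df["atrx"] = idh1, codel, atrx
    df["mgmt"], df["tp53"] = mgmt, tp53
    df["ki67_index"] = ki67
    df["tortuosity"] = tort
    if spec.include_missing:
        for var, col in [("idh1", "idh1"), ("chr1p19q", "chr1p19q"),
                         ("atrx", "atrx"), ("mgmt", "mgmt"), ("tp53", "tp53"),
                         ("ki67", "ki67_index")]:
            p_obs = np.where(shape == "C", _obs_p(var, "C"), _obs_p(var, "L"))
            missing = rng.random(n) >= p_obs
            df.loc[missing, col] = np.nan
    return df


def make_reference_cohort() -> pd.DataFrame:
    """Deterministic cohort whose per-variable 2x2 tables are exactly the
    published counts.

    Each variable's levels are dealt independently within the two shape
    groups (161 linear, 169 curved) so that every marginal table — but not
    any joint distribution — matches the publication exactly.  Cells beyond
    a variable's subtotal are missing, mirroring the published subtotals.
    No survival columns: this cohort exists for the association suite.
    """
    shape = np.array(["L"] * N_LINEAR + ["C"] * N_CURVED)
    n = len(shape)
    df = pd.DataFrame({"id": [f"T{i:05d}" for i in range(n)],
                       "shape_label": shape})

    def deal(var: str, mapper=None) -> np.ndarray:
        row = PUBLISHED_MARGINS[var]
        out = np.full(n, np.nan, dtype=object)
        for grp, key, total in [("L", "L", N_LINEAR), ("C", "C", N_CURVED)]:
            idx = np.flatnonzero(shape == grp)
            c1, c2 = row[key]
            levels = row["levels"] if mapper is None else mapper
            vals = [levels[0]] * c1 + [levels[1]] * c2
            out[idx[: len(vals)]] = vals
        return out

    df["age"] = [18.0 if v == "<=38" else 50.0 for v in deal("age")]
    df["gender"] = deal("gender")
    df["side"] = deal("side")
    df["volume"] = [10.0 if v == "<=20.17" else 40.0 for v in deal("volume")]
    df["histology"] = deal("histology")
    df["who_grade"] = deal("who_grade")
    df["idh1"] = deal("idh1")
    df["chr1p19q"] = deal("chr1p19q")
    df["idh1_with_1p19q"] = deal("idh1_with_1p19q")
    df["atrx"] = deal("atrx")
    df["mgmt"] = deal("mgmt")
    df["tp53"] = deal("tp53")
    df["ki67_index"] = [0.05 if v == "<=10%" else 0.30 if isinstance(v, str)
                        else np.nan for v in deal("ki67")]
    df["epilepsy"] = deal("epilepsy")
    return df


# --------------------------------------------------------------------------
# worked survival fixtures
# --------------------------------------------------------------------------

def make_survival_fixture(name: str) -> pd.DataFrame:
    """Small hand-checkable survival record sets.

    ``km4``: 4 records, events at t = 1, 2, 3, 4 — the product-limit curve
    steps by 1/4 at each time; the median is 2.

    ``km6cens``: 6 records, censored at t = 2.5 and 5.5.  Hand-worked
    product-limit table (d events of n at risk):
        t=1: 1/6 -> S = 5/6
        t=3: 1/4 -> S = 5/6 * 3/4 = 5/8
        t=4: 1/3 -> S = 5/8 * 2/3 = 5/12
        t=6: 1/1 -> S = 0

    ``lr-balanced``: two identical groups of 4 (group column g) — any
    two-sample log-rank statistic is exactly 0.
    """
    if name == "km4":
        return pd.DataFrame({"pfs_months": [1.0, 2.0, 3.0, 4.0],
                             "event": [1, 1, 1, 1]})
    if name == "km6cens":
        return pd.DataFrame({"pfs_months": [1.0, 2.5, 3.0, 4.0, 5.5, 6.0],
                             "event": [1, 0, 1, 1, 0, 1]})
    if name == "lr-balanced":
        half = pd.DataFrame({"pfs_months": [1.0, 2.0, 3.0, 4.0],
                             "event": [1, 1, 0, 1]})
        both = pd.concat([half.assign(g="a"), half.assign(g="b")],
                         ignore_index=True)
        return both
    raise GlioshapeError("unknown-fixture", f"unknown fixture {name!r}")
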