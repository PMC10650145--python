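"""Exhaustive coarse-to-fine search over index formulas.

The candidate space is every coefficient 6-tuple over a configured integer
set crossed with every ordered wavelength triple on a strided band grid, for
one or both formula families.  Sign-symmetric duplicates are excluded by a
lexicographic canonicalization (a ratio-family tuple is emitted only if it
precedes its full negation; a product_ratio tuple only if its denominator
half precedes its negation), and tuples with an all-zero numerator or
denominator are dropped as degenerate.

Each candidate is scored by evaluating its index image, normalizing to
[0, 1] with percentile clipping, and taking the masked RMS against the
expert vessel mask under the better polarity.  Candidates whose image is
constant over valid pixels are rejected outright: a constant image
normalizes to 0 and would otherwise score a fake-perfect RMS while carrying
no vessel information.  Among results whose RMS ties the best within a
tolerance, ranking falls back to average Michelson contrast, descending.

The hot path is vectorized per wavelength triple (all coefficient tuples at
once) but performs the same arithmetic, in the same order, as the public
``eval_* -> normalize_index -> masked_rms`` composition, so a brute-force
loop over :func:`enumerate_candidates` reproduces its scores.
"""

from __future__ import annotations

import itertools
import logging
import math
import time
from dataclasses import dataclass

import numpy as np

from .contrast import average_contrast
from .errors import ContrastError, MaskError, SearchError
from .hypercube import Hypercube, band_at
from .indices import (
    COEFF_SET_DEFAULT,
    IndexFormula,
    IndexImage,
    _linear,
    denominator_validity,
    eval_index,
    normalize_index,
)
from .reference import MAX_INVALID_VESSEL_FRACTION, ObjectiveScore, VesselMask, masked_rms

__all__ = [
    "SearchConfig",
    "SearchResult",
    "nominal_candidate_count",
    "enumerate_candidates",
    "count_candidates",
    "score_formula",
    "search",
    "refine",
    "baseline_two_wavelength",
]

logger = logging.getLogger("veinindex.search")


@dataclass
class SearchConfig:
    """Knobs of the exhaustive search."""

    families: tuple[str, ...] = ("ratio", "product_ratio")
    coefficient_set: tuple[int, ...] = COEFF_SET_DEFAULT
    wavelength_stride: int = 25
    refine_top: int = 10
    refine_halfwidth_bands: int | None = None  # defaults to the stride
    rms_tie_tolerance: float = 0.01
    keep_top: int | None = 50
    clip_percentiles: tuple[float, float] = (1.0, 99.0)
    tie_break_contrast: bool = True
    contrast_tie_limit: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        self.families = tuple(self.families)
        for fam in self.families:
            if fam not in ("ratio", "product_ratio"):
                raise SearchError(f"unknown family '{fam}'")
        if not self.families:
            raise SearchError("at least one formula family required")
        cset = tuple(sorted(set(int(c) for c in self.coefficient_set)))
        if not cset:
            raise SearchError("coefficient set must be nonempty")
        if set(cset) != {-c for c in cset}:
            raise SearchError("coefficient set must be symmetric about 0")
        if not any(c != 0 for c in cset):
            raise SearchError("coefficient set must contain a nonzero value")
        self.coefficient_set = cset
        if self.wavelength_stride < 1:
            raise SearchError("wavelength stride must be >= 1")
        if self.refine_top < 1:
            raise SearchError("refine_top must be >= 1")

    @property
    def halfwidth(self) -> int:
        return self.refine_halfwidth_bands if self.refine_halfwidth_bands is not None else self.wavelength_stride


@dataclass
class SearchResult:
    formula: IndexFormula
    rms: float
    polarity: str
    avg_contrast: float  # NaN when not evaluated (outside the tie set)
    rank: int


def nominal_candidate_count(config: SearchConfig, n_bands: int, symmetry_reduced: bool = True) -> float:
    """The arithmetic size of the candidate grid for one family.

    With symmetry reduction: 0.5 · |set|^6 · ceil(n_bands / stride)^3.
    Without (full grid at stride 1 this reduces to |set|^6 · n_bands^3).
    """
    if n_bands < 1:
        raise SearchError("n_bands must be >= 1")
    s = len(config.coefficient_set)
    grid = math.ceil(n_bands / config.wavelength_stride)
    total = float(s) ** 6 * float(grid) ** 3
    return 0.5 * total if symmetry_reduced else total


def _neg(t: tuple[int, ...]) -> tuple[int, ...]:
    return tuple(-x for x in t)


class _FamilyTable:
    """Canonical coefficient tuples for one family, organized num-major."""

    def __init__(self, family: str, cset: tuple[int, ...]):
        self.family = family
        triples = list(itertools.product(cset, repeat=3))
        nonzero = [t for t in triples if any(t)]
        if family == "ratio":
            self.nums = [t for t in nonzero if t < _neg(t)]
            self.dens = nonzero
        else:
            self.nums = nonzero
            self.dens = [t for t in nonzero if t < _neg(t)]
        # tuple order matches itertools.product(cset, repeat=6) filtered
        self.tuples: list[tuple[int, ...]] = [n + d for n in self.nums for d in self.dens]

    def num_rows(self, i1: np.ndarray, i2: np.ndarray, i3: np.ndarray) -> np.ndarray:
        if self.family == "ratio":
            return np.stack([_linear(n[0], n[1], n[2], i1, i2, i3) for n in self.nums])
        # product_ratio: (k1·I1 + k2·I2)·(k1·I1 + k3·I3), k1 shared as printed
        f12: dict[tuple[int, int], np.ndarray] = {}
        f13: dict[tuple[int, int], np.ndarray] = {}
        rows = []
        for k1, k2, k3 in self.nums:
            a = f12.setdefault((k1, k2), k1 * i1 + k2 * i2)
            b = f13.setdefault((k1, k3), k1 * i1 + k3 * i3)
            rows.append(a * b)
        return np.stack(rows)

    def den_rows(self, i1: np.ndarray, i2: np.ndarray, i3: np.ndarray) -> np.ndarray:
        return np.stack([_linear(d[0], d[1], d[2], i1, i2, i3) for d in self.dens])


def _is_canonical(family: str, k: tuple[int, ...]) -> bool:
    num, den = k[:3], k[3:]
    if not any(num) or not any(den):
        return False
    if family == "ratio":
        return k < _neg(k)
    return den < _neg(den)


def _canonicalize(family: str, k: tuple[int, ...]) -> tuple[int, ...] | None:
    """Map a tuple onto its canonical sign representative; None if degenerate."""
    num, den = k[:3], k[3:]
    if not any(num) or not any(den):
        return None
    if family == "ratio":
        return k if k < _neg(k) else _neg(k)
    return k if den < _neg(den) else num + _neg(den)


def _grid_indices(n_bands: int, stride: int) -> np.ndarray:
    return np.arange(0, n_bands, stride)


def enumerate_candidates(config: SearchConfig, wavelengths_nm: np.ndarray):
    """Yield every canonical candidate formula over the strided grid.

    Wavelength triples are ordered draws (repeats allowed) from the strided
    axis; a formula and its sign-symmetric duplicate never both appear.
    """
    w = np.asarray(wavelengths_nm, dtype=np.float64)
    if w.ndim != 1 or np.any(np.diff(w) <= 0):
        raise SearchError("wavelength axis must be 1-D and strictly increasing")
    grid = _grid_indices(len(w), config.wavelength_stride)
    for family in config.families:
        table = _FamilyTable(family, config.coefficient_set)
        for a, b, c in itertools.product(grid, repeat=3):
            lambdas = (float(w[a]), float(w[b]), float(w[c]))
            for k in table.tuples:
                yield IndexFormula(family=family, lambdas_nm=lambdas, coeffs=k)


def count_candidates(config: SearchConfig, n_bands: int) -> int:
    """Actual number of candidates emitted (degenerate tuples removed)."""
    grid = len(_grid_indices(n_bands, config.wavelength_stride))
    total = 0
    for family in config.families:
        total += len(_FamilyTable(family, config.coefficient_set).tuples) * grid ** 3
    return total


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def score_formula(
    cube: Hypercube,
    mask: VesselMask,
    formula: IndexFormula,
    clip_percentiles: tuple[float, float] = (1.0, 99.0),
) -> ObjectiveScore | None:
    """Score one candidate through the public ops; None when rejected.

    Rejection covers: all pixels invalid, constant image over valid pixels
    (zero percentile range), or more than half of the vessel pixels invalid.
    """
    img = eval_index(cube, formula)
    if not img.valid.any():
        return None
    vals = img.values[img.valid]
    lo, hi = np.percentile(vals, clip_percentiles)
    if not hi > lo:
        return None
    nimg = normalize_index(img, clip_percentiles)
    try:
        return masked_rms(nimg, mask)
    except MaskError:
        return None


def _percentiles_sorted_rows(S: np.ndarray, qs) -> list[np.ndarray]:
    """Per-row percentiles from row-sorted data.

    Reproduces ``np.percentile(..., axis=1)`` (linear interpolation)
    bit-exactly, including its midpoint-switched lerp.
    """
    n = S.shape[1]
    out = []
    for q in qs:
        pos = (n - 1) * (q / 100.0)
        f = int(np.floor(pos))
        c = min(f + 1, n - 1)
        t = pos - f
        a, b = S[:, f], S[:, c]
        d = b - a
        r = b - d * (1.0 - t) if t >= 0.5 else a + d * t
        out.append(r)
    return out


def _score_rows_all_valid(R: np.ndarray, vessel_idx: np.ndarray, clip_q) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Score rows of R (candidates × pixels) when every pixel is valid."""
    lo, hi = _percentiles_sorted_rows(np.sort(R, axis=1), clip_q)
    rng = hi - lo
    ok = rng > 0
    safe = np.where(ok, rng, 1.0)
    v = R[:, vessel_idx]
    np.clip(v, lo[:, None], hi[:, None], out=v)
    vn = (v - lo[:, None]) / safe[:, None]
    rms_dark = np.sqrt(np.mean(vn ** 2, axis=1))
    rms_bright = np.sqrt(np.mean((1.0 - vn) ** 2, axis=1))
    dark = rms_dark <= rms_bright
    rms = np.where(dark, rms_dark, rms_bright)
    rms = np.where(ok, rms, np.inf)
    return rms, dark, ok


def _score_row_partial(
    row: np.ndarray,
    valid: np.ndarray,
    vessel_idx: np.ndarray,
    n_vessel_total: int,
    clip_q,
) -> tuple[float, bool, bool]:
    """Score one candidate whose denominator invalidates some pixels."""
    vals = row[valid]
    if vals.size == 0:
        return np.inf, True, False
    lo, hi = np.percentile(vals, clip_q)
    if not hi > lo:
        return np.inf, True, False
    sv = valid[vessel_idx]
    n = int(sv.sum())
    if n == 0 or 1.0 - n / n_vessel_total > MAX_INVALID_VESSEL_FRACTION:
        return np.inf, True, False
    v = np.clip(row[vessel_idx[sv]], lo, hi)
    vn = (v - lo) / (hi - lo)
    rms_dark = float(np.sqrt(np.mean(vn ** 2)))
    rms_bright = float(np.sqrt(np.mean((1.0 - vn) ** 2)))
    if rms_dark <= rms_bright:
        return rms_dark, True, True
    return rms_bright, False, True


def _score_grid_triple(
    i1: np.ndarray,
    i2: np.ndarray,
    i3: np.ndarray,
    table: _FamilyTable,
    vessel_idx: np.ndarray,
    n_vessel_total: int,
    clip_q,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Score all coefficient tuples of one family for one wavelength triple.

    Candidate order matches ``table.tuples`` (num-major, den inner).
    """
    nums = table.num_rows(i1, i2, i3)  # (N, P)
    dens = table.den_rows(i1, i2, i3)  # (D, P)
    n_num, n_den = nums.shape[0], dens.shape[0]
    valid_per_den = [denominator_validity(dens[d]) for d in range(n_den)]
    fully_valid = [bool(v.all()) for v in valid_per_den]

    with np.errstate(divide="ignore", invalid="ignore"):
        R = (nums[:, None, :] / dens[None, :, :]).reshape(n_num * n_den, -1)

    if all(fully_valid):
        return _score_rows_all_valid(R, vessel_idx, clip_q)

    rms = np.full(n_num * n_den, np.inf)
    dark = np.ones(n_num * n_den, dtype=bool)
    ok = np.zeros(n_num * n_den, dtype=bool)
    for d in range(n_den):
        idx = np.arange(d, n_num * n_den, n_den)
        if fully_valid[d]:
            r, p, o = _score_rows_all_valid(np.ascontiguousarray(R[idx]), vessel_idx, clip_q)
            rms[idx], dark[idx], ok[idx] = r, p, o
        else:
            vmask = valid_per_den[d]
            for ni, gi in enumerate(idx):
                rms[gi], dark[gi], ok[gi] = _score_row_partial(
                    R[gi], vmask, vessel_idx, n_vessel_total, clip_q
                )
    return rms, dark, ok


def _candidate_contrast(cube: Hypercube, formula: IndexFormula, polarity: str, clip_q) -> float:
    """Average Michelson contrast of the candidate's dark-oriented normalized image."""
    img = eval_index(cube, formula)
    if not img.valid.any():
        return 0.0
    nimg = normalize_index(img, clip_q)
    values = nimg.values
    if polarity == "vessels_bright":
        values = np.where(nimg.valid, 1.0 - values, 0.0)
    oriented = IndexImage(values=values, valid=nimg.valid, normalized=True)
    try:
        return average_contrast(oriented).mean_contrast
    except ContrastError:
        return 0.0


def _rank_entries(cube: Hypercube, entries: list[dict], config: SearchConfig) -> list[SearchResult]:
    """Sort candidate entries by RMS, tie-break the top group by contrast.

    Each entry carries ``formula``, ``rms``, ``polarity`` and a deterministic
    ``order`` key (enumeration index).  Entries within ``rms_tie_tolerance``
    of the best get their average contrast computed and are ranked by it,
    descending; everything else ranks by (rms, order).
    """
    if not entries:
        raise SearchError("no scoreable candidates")
    entries = sorted(entries, key=lambda e: (e["rms"], e["order"]))
    best = entries[0]["rms"]
    n_tie = sum(1 for e in entries if e["rms"] <= best + config.rms_tie_tolerance)
    results: list[SearchResult] = []
    if config.tie_break_contrast and n_tie > 1:
        n_eval = min(n_tie, config.contrast_tie_limit)
        for e in entries[:n_eval]:
            e["avg_contrast"] = _candidate_contrast(
                cube, e["formula"], e["polarity"], config.clip_percentiles
            )
        tie = sorted(
            entries[:n_eval],
            key=lambda e: (-e["avg_contrast"], e["rms"], e["order"]),
        )
        ordered = tie + entries[n_eval:]
    else:
        ordered = entries
    for rank, e in enumerate(ordered, start=1):
        results.append(
            SearchResult(
                formula=e["formula"],
                rms=float(e["rms"]),
                polarity=e["polarity"],
                avg_contrast=float(e.get("avg_contrast", np.nan)),
                rank=rank,
            )
        )
    return results


def search(cube: Hypercube, mask: VesselMask, config: SearchConfig) -> list[SearchResult]:
    """Exhaustive search over the strided candidate grid; ranked results.

    Deterministic: identical inputs produce identical output.  Returns at
    most ``config.keep_top`` results (all scoreable candidates when None).
    """
    if mask.values.shape != cube.values.shape[:2]:
        raise MaskError("mask shape does not match cube spatial grid")
    if mask.is_empty:
        raise MaskError("empty vessel mask cannot drive the search")
    B = cube.n_bands
    grid = _grid_indices(B, config.wavelength_stride)
    if len(grid) == 0:
        raise SearchError("empty candidate stream: no grid wavelengths")

    bands_T = np.ascontiguousarray(cube.values.reshape(-1, B).T)  # (B, P)
    vessel_idx = np.flatnonzero(mask.values.ravel())
    n_vessel = len(vessel_idx)
    clip_q = config.clip_percentiles

    rms_parts: list[np.ndarray] = []
    dark_parts: list[np.ndarray] = []
    ok_parts: list[np.ndarray] = []
    blocks: list[tuple[str, tuple[int, int, int], int]] = []  # family, triple, offset
    offset = 0
    t0 = time.monotonic()
    n_triples_total = len(config.families) * len(grid) ** 3
    n_done = 0
    for family in config.families:
        table = _FamilyTable(family, config.coefficient_set)
        for a, b, c in itertools.product(grid, repeat=3):
            r, p, o = _score_grid_triple(
                bands_T[a], bands_T[b], bands_T[c], table, vessel_idx, n_vessel, clip_q
            )
            rms_parts.append(r)
            dark_parts.append(p)
            ok_parts.append(o)
            blocks.append((family, (int(a), int(b), int(c)), offset))
            offset += len(r)
            n_done += 1
            if n_done % 500 == 0:
                rate = offset / max(time.monotonic() - t0, 1e-9)
                logger.info(
                    "search: %d/%d triples, %d candidates, %.0f cand/s",
                    n_done, n_triples_total, offset, rate,
                )

    rms_all = np.concatenate(rms_parts)
    dark_all = np.concatenate(dark_parts)
    ok_all = np.concatenate(ok_parts)
    logger.info(
        "search: scored %d candidates (%d rejected) in %.1f s",
        len(rms_all), int((~ok_all).sum()), time.monotonic() - t0,
    )
    if not ok_all.any():
        raise SearchError("no scoreable candidates (all rejected)")

    order = np.argsort(rms_all, kind="stable")
    n_keep = int(ok_all.sum()) if config.keep_top is None else min(config.keep_top, int(ok_all.sum()))
    top = order[:n_keep]

    offsets = np.array([blk[2] for blk in blocks])
    w = cube.wavelengths_nm
    tuples_by_family = {
        fam: _FamilyTable(fam, config.coefficient_set).tuples for fam in config.families
    }
    entries = []
    for g in top:
        bi = int(np.searchsorted(offsets, g, side="right") - 1)
        family, (a, b, c), off = blocks[bi]
        k = tuples_by_family[family][g - off]
        formula = IndexFormula(
            family=family,
            lambdas_nm=(float(w[a]), float(w[b]), float(w[c])),
            coeffs=k,
        )
        entries.append(
            {
                "formula": formula,
                "rms": float(rms_all[g]),
                "polarity": "vessels_dark" if dark_all[g] else "vessels_bright",
                "order": int(g),
            }
        )
    return _rank_entries(cube, entries, config)


# ---------------------------------------------------------------------------
# Refinement
# ---------------------------------------------------------------------------

def _coeff_neighborhood(family: str, k: tuple[int, ...], cset: tuple[int, ...]) -> list[tuple[int, ...]]:
    """The coarse tuple plus every one-step-per-coefficient variant, canonicalized."""
    variants = [k]
    for pos in range(6):
        ci = cset.index(k[pos])
        for step in (-1, 1):
            j = ci + step
            if 0 <= j < len(cset):
                variants.append(k[:pos] + (cset[j],) + k[pos + 1:])
    out: list[tuple[int, ...]] = []
    for v in variants:
        cv = _canonicalize(family, v)
        if cv is not None and cv not in out:
            out.append(cv)
    return out


def _score_tuples_at(
    bands_T: np.ndarray,
    triple: tuple[int, int, int],
    family: str,
    tuples: list[tuple[int, ...]],
    vessel_idx: np.ndarray,
    n_vessel: int,
    clip_q,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Score an arbitrary small tuple list at one wavelength triple."""
    from .indices import _product_numerator

    i1, i2, i3 = bands_T[triple[0]], bands_T[triple[1]], bands_T[triple[2]]
    rows = []
    dens = []
    for k in tuples:
        if family == "ratio":
            rows.append(_linear(k[0], k[1], k[2], i1, i2, i3))
        else:
            rows.append(_product_numerator(k[0], k[1], k[2], i1, i2, i3))
        dens.append(_linear(k[3], k[4], k[5], i1, i2, i3))
    rms = np.full(len(tuples), np.inf)
    dark = np.ones(len(tuples), dtype=bool)
    ok = np.zeros(len(tuples), dtype=bool)
    all_valid_rows = []
    all_valid_pos = []
    for i, (num, den) in enumerate(zip(rows, dens)):
        valid = denominator_validity(den)
        with np.errstate(divide="ignore", invalid="ignore"):
            r = num / den
        if valid.all():
            all_valid_rows.append(r)
            all_valid_pos.append(i)
        else:
            rms[i], dark[i], ok[i] = _score_row_partial(r, valid, vessel_idx, n_vessel, clip_q)
    if all_valid_rows:
        rr, pp, oo = _score_rows_all_valid(np.stack(all_valid_rows), vessel_idx, clip_q)
        pos = np.array(all_valid_pos)
        rms[pos], dark[pos], ok[pos] = rr, pp, oo
    return rms, dark, ok


def refine(
    cube: Hypercube,
    mask: VesselMask,
    coarse_results: list[SearchResult],
    config: SearchConfig,
) -> list[SearchResult]:
    """Stride-1 refinement of the most promising coarse results.

    For each of the top ``refine_top`` coarse results, the three wavelengths
    are refined by coordinate descent: each axis in turn scans every band
    within ±``refine_halfwidth_bands`` of the current position (stride 1),
    jointly with the coarse tuple's one-step coefficient neighborhood, and
    moves only on strict improvement.  Up to three sweeps.  The coarse point
    is always a candidate, so the refined RMS never exceeds the coarse RMS.
    Returns the merged, re-ranked coarse + refined results.
    """
    if not coarse_results:
        raise SearchError("refine needs a nonempty coarse result list")
    B = cube.n_bands
    bands_T = np.ascontiguousarray(cube.values.reshape(-1, B).T)
    vessel_idx = np.flatnonzero(mask.values.ravel())
    n_vessel = len(vessel_idx)
    clip_q = config.clip_percentiles
    h = config.halfwidth
    w = cube.wavelengths_nm

    refined_entries: list[dict] = []
    for ri, res in enumerate(coarse_results[: config.refine_top]):
        triple = tuple(band_at(cube, lam).band_index for lam in res.formula.lambdas_nm)
        tuples = _coeff_neighborhood(res.formula.family, res.formula.coeffs, config.coefficient_set)
        # current state
        cur_triple = triple
        cur_tuple_i = tuples.index(_canonicalize(res.formula.family, res.formula.coeffs))
        cur_rms, cur_dark = np.inf, True
        r0, p0, o0 = _score_tuples_at(
            bands_T, cur_triple, res.formula.family, tuples, vessel_idx, n_vessel, clip_q
        )
        if o0[cur_tuple_i]:
            cur_rms, cur_dark = float(r0[cur_tuple_i]), bool(p0[cur_tuple_i])
        for _sweep in range(3):
            moved = False
            for axis in range(3):
                lo_b = max(0, cur_triple[axis] - h)
                hi_b = min(B - 1, cur_triple[axis] + h)
                for band in range(lo_b, hi_b + 1):
                    cand_triple = tuple(
                        band if ax == axis else cur_triple[ax] for ax in range(3)
                    )
                    r, p, o = _score_tuples_at(
                        bands_T, cand_triple, res.formula.family, tuples,
                        vessel_idx, n_vessel, clip_q,
                    )
                    r = np.where(o, r, np.inf)
                    ti = int(np.argmin(r))
                    if r[ti] < cur_rms:
                        cur_rms, cur_dark = float(r[ti]), bool(p[ti])
                        cur_triple, cur_tuple_i = cand_triple, ti
                        moved = True
            if not moved:
                break
        if np.isfinite(cur_rms):
            formula = IndexFormula(
                family=res.formula.family,
                lambdas_nm=tuple(float(w[b]) for b in cur_triple),
                coeffs=tuples[cur_tuple_i],
            )
            refined_entries.append(
                {
                    "formula": formula,
                    "rms": cur_rms,
                    "polarity": "vessels_dark" if cur_dark else "vessels_bright",
                    "order": 10 ** 9 + ri,  # after all coarse enumeration keys
                }
            )
        logger.info("refine: result %d -> rms %.5f at bands %s", ri + 1, cur_rms, cur_triple)

    merged: dict[tuple, dict] = {}
    for i, res in enumerate(coarse_results):
        key = (res.formula.family, res.formula.lambdas_nm, res.formula.coeffs)
        merged[key] = {
            "formula": res.formula,
            "rms": res.rms,
            "polarity": res.polarity,
            "order": i,
        }
    for e in refined_entries:
        key = (e["formula"].family, e["formula"].lambdas_nm, e["formula"].coeffs)
        if key not in merged or e["rms"] < merged[key]["rms"]:
            merged[key] = e
    return _rank_entries(cube, list(merged.values()), config)


def baseline_two_wavelength(
    cube: Hypercube,
    mask: VesselMask,
    config: SearchConfig | None = None,
) -> SearchResult:
    """Best normalized-difference index (I_a − I_b)/(I_a + I_b) over the grid.

    Two-wavelength indices are degenerate members of the ratio family
    (k = (1, −1, 0, 1, 1, 0)); this is the comparison baseline against which
    the three-wavelength improvement is measured.
    """
    if config is None:
        config = SearchConfig()
    if mask.is_empty:
        raise MaskError("empty vessel mask cannot drive the baseline search")
    B = cube.n_bands
    grid = _grid_indices(B, config.wavelength_stride)
    if len(grid) < 2:
        raise SearchError("need at least two grid wavelengths for the baseline")
    w = cube.wavelengths_nm
    best: tuple[float, int, IndexFormula, str] | None = None
    order = 0
    for a, b in itertools.combinations(grid, 2):
        formula = IndexFormula(
            family="ratio",
            lambdas_nm=(float(w[a]), float(w[b]), float(w[a])),
            coeffs=(1, -1, 0, 1, 1, 0),
        )
        score = score_formula(cube, mask, formula, config.clip_percentiles)
        order += 1
        if score is None:
            continue
        if best is None or score.rms < best[0]:
            best = (score.rms, order, formula, score.polarity)
    if best is None:
        raise SearchError("no scoreable two-wavelength pair")
    rms, _, formula, polarity = best
    contrast = _candidate_contrast(cube, formula, polarity, config.clip_percentiles)
    return SearchResult(formula=formula, rms=rms, polarity=polarity, avg_contrast=contrast, rank=1)
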