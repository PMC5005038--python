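"""Hexagonal task geometry, counterbalanced trial designs and pair labels.

The direction-imagination task samples twelve evenly spaced directions
(30 degrees apart) between 18 buildings whose entrances sit on the vertices
of equilateral triangles arranged in a hexagon.  The six buildings on the
innermost ring serve as start locations; from each start, ten of the twelve
directions can be sampled exactly.  Everything downstream -- pattern
similarity conditions, exclusion filters, distance controls -- is defined on
quantities derived here.

Coordinates are in lattice units (triangle side = 1) with north along +y.
A configurable ``scale`` converts lattice units to meters but is never
applied to the stored coordinates: all distance-based controls are
scale-invariant after GLM standardisation.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CityLayout",
    "TimingParams",
    "DesignError",
    "DesignSolverError",
    "build_city_layout",
    "enumerate_combinations",
    "apply_exclusions",
    "generate_design",
    "label_pairs",
    "wrapped_delta_deg",
    "pair_delta_matrix",
    "validate_design",
]

#: the twelve sampled directions, degrees counterclockwise from east (+x)
DIRECTIONS_DEG = tuple(range(0, 360, 30))
#: cardinal directions in layout coordinates (north = +y = 90 degrees)
CARDINAL_DEG = (0, 90, 180, 270)

N_BUILDINGS = 18
N_STARTS = 6
N_TRIALS = 96
N_BLOCKS = 4
TRIALS_PER_BLOCK = 24
CATCH_PER_BLOCK = 3

_BUILDING_NAMES = (
    "Alder Works", "Basalt House", "Cobble Court", "Drossel Hall",
    "Ember Depot", "Fennel Lodge", "Garnet Annex", "Heron Stack",
    "Iris Pavilion", "Juniper Gate", "Kestrel Yard", "Lantern Row",
    "Marrow Mill", "Nimbus Tower", "Osprey Block", "Pumice Forge",
    "Quill Archive", "Rowan Terrace",
)


class DesignError(ValueError):
    """A structural problem with a layout, combination set or trial table."""


class DesignSolverError(DesignError):
    """The constraint solver could not satisfy the counterbalancing rules."""


@dataclass(frozen=True)
class CityLayout:
    """Building positions on the triangular-lattice hexagon.

    ``buildings`` has one row per building with columns
    ``id, label, x, y, ring`` (``ring`` is ``inner`` or ``outer``).
    """

    buildings: pd.DataFrame
    north_axis: str = "+y"
    scale: float = 1.0

    def coords(self) -> dict[int, np.ndarray]:
        return {
            int(r.id): np.array([r.x, r.y])
            for r in self.buildings.itertuples(index=False)
        }

    @property
    def inner_ids(self) -> list[int]:
        return [int(i) for i in self.buildings.loc[self.buildings.ring == "inner", "id"]]

    def to_json(self, path) -> None:
        payload = {
            "north_axis": self.north_axis,
            "scale": self.scale,
            "buildings": self.buildings.to_dict(orient="records"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "CityLayout":
        with open(path) as fh:
            payload = json.load(fh)
        df = pd.DataFrame(payload["buildings"], columns=["id", "label", "x", "y", "ring"])
        return cls(buildings=df, north_axis=payload["north_axis"], scale=payload["scale"])


@dataclass(frozen=True)
class TimingParams:
    """Trial timing in seconds; one fMRI run per task block."""

    cue_s: float = 2.0
    imagination_s: float = 10.0
    response_s: float = 4.0
    confidence_s: float = 2.0
    catch_probe_s: float = 2.0
    iti_choices_s: tuple[float, ...] = (1.8, 3.6, 5.4)
    lead_in_s: float = 6.0


def build_city_layout(scale: float = 1.0, north_axis: str = "+y") -> CityLayout:
    """The 18-building layout: a side-2 triangular-lattice hexagon, center excluded.

    Six inner buildings sit at unit radius on the 0, 60, ..., 300 degree
    axes (the starts); six outer buildings at radius 2 on the same axes and
    six at radius sqrt(3) on the 30-degree-offset axes.
    """
    if scale <= 0:
        raise DesignError("scale must be positive")
    if north_axis != "+y":
        raise DesignError("only north_axis='+y' is supported")
    rows = []
    idx = 0

    def _add(radius: float, angle_deg: float, ring: str) -> None:
        nonlocal idx
        a = np.deg2rad(angle_deg)
        rows.append(
            {
                "id": idx + 1,
                "label": _BUILDING_NAMES[idx],
                "x": round(radius * np.cos(a), 12),
                "y": round(radius * np.sin(a), 12),
                "ring": ring,
            }
        )
        idx += 1

    for k in range(6):
        _add(1.0, 60 * k, "inner")
    for k in range(6):
        _add(np.sqrt(3.0), 60 * k + 30, "outer")
    for k in range(6):
        _add(2.0, 60 * k, "outer")
    return CityLayout(buildings=pd.DataFrame(rows), north_axis=north_axis, scale=scale)


def _snap_direction(dx: float, dy: float, tol: float = 1e-9) -> int | None:
    """Angle of (dx, dy) in degrees if it is a multiple of 30, else None."""
    ang = np.degrees(np.arctan2(dy, dx)) % 360.0
    snapped = round(ang / 30.0) * 30 % 360
    return int(snapped) if abs(ang - snapped) < max(tol, 1e-6) else None


def _check_layout(layout: CityLayout) -> None:
    b = layout.buildings
    if len(b) != N_BUILDINGS or (b.ring == "inner").sum() != N_STARTS:
        raise DesignError("layout must have 18 buildings with 6 inner starts")


def enumerate_combinations(layout: CityLayout) -> pd.DataFrame:
    """All sampled start->target combinations on the 30-degree direction grid.

    From every inner start, each direction reachable toward some building is
    represented once; when an inner and an outer building lie on the same ray
    the outer one is the target, which keeps inner-ring targets confined to
    the 30-mod-60 directions.  Directions that are not exact multiples of 30
    degrees are discarded.  Returns 60 combinations (10 per start).
    """
    _check_layout(layout)
    coords = layout.coords()
    ring = dict(zip(layout.buildings.id.astype(int), layout.buildings.ring))
    rows = []
    for s in layout.inner_ids:
        by_dir: dict[int, list[int]] = {}
        for t in coords:
            if t == s:
                continue
            d = _snap_direction(*(coords[t] - coords[s]))
            if d is not None:
                by_dir.setdefault(d, []).append(t)
        for d, targets in sorted(by_dir.items()):
            if len(targets) > 1:
                outer = [t for t in targets if ring[t] == "outer"]
                if len(outer) != 1:
                    raise DesignError(
                        f"ambiguous target choice from start {s} along {d} deg"
                    )
                tgt = outer[0]
            else:
                tgt = targets[0]
            rows.append(
                {
                    "start_id": s,
                    "target_id": tgt,
                    "direction_deg": d,
                    "target_ring": ring[tgt],
                    "main_axis": d % 60 == 0,
                }
            )
    combos = pd.DataFrame(rows)
    if len(combos) != 60:
        raise DesignError(f"expected 60 combinations, got {len(combos)}")
    return combos


def apply_exclusions(
    combinations: pd.DataFrame, seed: int | np.random.Generator
) -> pd.DataFrame:
    """Drop 12 of the 60 combinations so every direction is sampled 4 times.

    The six main-axis directions (multiples of 60 degrees) are available from
    all six starts and hence oversampled; two of their combinations are
    removed per direction, under the constraint that exactly two combinations
    are removed per start.  Seeded and reproducible.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    main = combinations[combinations.main_axis]
    offs = combinations[~combinations.main_axis]
    dirs = sorted(main.direction_deg.unique())
    starts = sorted(combinations.start_id.unique())
    if len(dirs) != 6 or any((main.direction_deg == d).sum() != 6 for d in dirs):
        raise DesignError("main-axis directions must each be available from 6 starts")
    if any((offs.direction_deg == d).sum() != 4 for d in sorted(offs.direction_deg.unique())):
        raise DesignError("off-axis directions must each be available from 4 starts")
    # Two disjoint random bijections directions -> starts remove 2 combos per
    # direction and 2 per start simultaneously.
    perm1 = rng.permutation(starts)
    for _ in range(10_000):
        perm2 = rng.permutation(starts)
        if np.all(perm1 != perm2):
            break
    else:  # pragma: no cover - probability ~0.63 per draw
        raise DesignSolverError("could not find disjoint exclusion matchings")
    drop = set(zip(np.r_[perm1, perm2], dirs * 2))
    keep = ~combinations.apply(
        lambda r: (r.start_id, r.direction_deg) in drop, axis=1
    )
    out = combinations[keep].reset_index(drop=True)
    if len(out) != 48:
        raise DesignSolverError("exclusion did not leave 48 combinations")
    return out


def _split_half(combos: pd.DataFrame, rng: np.random.Generator) -> np.ndarray:
    """Pick 24 of 48 combinations: 2 per direction and 4 per start.

    Randomised depth-first search over directions; each start may contribute
    at most 4 combinations, and with 24 picks over 6 starts the cap forces
    exactly 4 each.
    """
    dirs = list(rng.permutation(sorted(combos.direction_deg.unique())))
    per_dir = {d: combos.index[combos.direction_deg == d].to_numpy() for d in dirs}
    start_of = combos.start_id.to_dict()
    counts: dict[int, int] = {}
    chosen: list[int] = []

    def dfs(i: int) -> bool:
        if i == len(dirs):
            return True
        idxs = per_dir[dirs[i]]
        pairs = list(itertools.combinations(idxs, 2))
        rng.shuffle(pairs)
        for a, b in pairs:
            sa, sb = start_of[a], start_of[b]
            tentative = dict(counts)
            tentative[sa] = tentative.get(sa, 0) + 1
            tentative[sb] = tentative.get(sb, 0) + 1
            if max(tentative.values()) > 4:
                continue
            counts.update(tentative)
            chosen.extend((a, b))
            if dfs(i + 1):
                return True
            del chosen[-2:]
            counts[sa] -= 1
            counts[sb] -= 1
        return False

    if not dfs(0):
        raise DesignSolverError(
            "no block split satisfies 2-per-direction / 4-per-start"
        )
    return np.asarray(chosen)


def generate_design(
    combinations48: pd.DataFrame,
    timing: TimingParams | None = None,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """The 96-trial, 4-block counterbalanced trial table.

    Blocks 1-2 use each of the 48 combinations once, as do blocks 3-4, so
    every combination occurs exactly twice overall.  Within each 24-trial
    block every direction is sampled twice and every start building is used
    four times; trial order is randomised within block.  Three catch trials
    per block (never the first trial) carry a 50%-correct snapshot probe and
    keep their normal direction labels.
    """
    timing = timing or TimingParams()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if len(combinations48) != 48:
        raise DesignError("expected 48 combinations")
    blocks: list[pd.DataFrame] = []
    for _half in range(2):
        first = _split_half(combinations48, rng)
        second = combinations48.index.difference(first).to_numpy()
        for idxs in (first, second):
            order = rng.permutation(idxs)
            blocks.append(combinations48.loc[order].reset_index(drop=True))

    catch_correct = rng.permutation([True] * 6 + [False] * 6)
    rows = []
    trial_id = 1
    for b, block in enumerate(blocks, start=1):
        catch_pos = set(rng.choice(np.arange(1, TRIALS_PER_BLOCK), size=CATCH_PER_BLOCK,
                                   replace=False))
        t = timing.lead_in_s
        ci = (b - 1) * CATCH_PER_BLOCK
        n_catch = 0
        for w, r in enumerate(block.itertuples(index=False)):
            is_catch = w in catch_pos
            cue_onset = t
            imag_end = cue_onset + timing.cue_s + timing.imagination_s
            rows.append(
                {
                    "trial_id": trial_id,
                    "block": b,
                    "within_block_index": w,
                    "start_id": r.start_id,
                    "target_id": r.target_id,
                    "direction_deg": r.direction_deg,
                    "is_catch": is_catch,
                    "catch_view_correct": bool(catch_correct[ci + n_catch]) if is_catch else False,
                    "cue_onset_s": round(cue_onset, 6),
                    "imagination_end_s": round(imag_end, 6),
                }
            )
            n_catch += is_catch
            t = (
                imag_end
                + (timing.catch_probe_s if is_catch else 0.0)
                + timing.response_s
                + timing.confidence_s
                + float(rng.choice(timing.iti_choices_s))
            )
            trial_id += 1
    trials = pd.DataFrame(rows)
    _assert_counterbalanced(trials)
    return trials


def _assert_counterbalanced(trials: pd.DataFrame) -> None:
    if len(trials) != N_TRIALS:
        raise DesignSolverError("trial table must have 96 trials")
    for b, block in trials.groupby("block"):
        if len(block) != TRIALS_PER_BLOCK:
            raise DesignSolverError(f"block {b} does not have 24 trials")
        if not (block.direction_deg.value_counts() == 2).all():
            raise DesignSolverError(f"block {b}: directions not sampled twice")
        if not (block.start_id.value_counts() == 4).all():
            raise DesignSolverError(f"block {b}: starts not used four times")
    combo_counts = trials.groupby(["start_id", "target_id"]).size()
    if not (combo_counts == 2).all():
        raise DesignSolverError("every combination must occur exactly twice")


def validate_design(trials: pd.DataFrame) -> list[str]:
    """Human-readable list of counterbalancing violations (empty if valid)."""
    try:
        _assert_counterbalanced(trials)
    except DesignSolverError as exc:
        return [str(exc)]
    problems = []
    if (trials.groupby("block").is_catch.sum() != CATCH_PER_BLOCK).any():
        problems.append("each block must contain 3 catch trials")
    per_dir = trials.direction_deg.value_counts()
    if not (per_dir == 8).all():
        problems.append("each direction must be sampled 8 times overall")
    return problems


def wrapped_delta_deg(a, b):
    """Minimal absolute angular difference, wrapped to [0, 180] degrees."""
    d = np.abs(np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % 360.0
    return np.minimum(d, 360.0 - d)


def pair_delta_matrix(directions_deg: np.ndarray) -> np.ndarray:
    """n x n matrix of wrapped angular differences between trial directions."""
    th = np.asarray(directions_deg, dtype=float)
    return wrapped_delta_deg(th[:, None], th[None, :])


def label_pairs(
    trials: pd.DataFrame,
    layout: CityLayout,
    ns_street_column_x: float = 1.0,
) -> pd.DataFrame:
    """Labels for all C(96, 2) unordered trial pairs.

    Columns: trial indices ``i < j`` (positional), wrapped angular difference
    ``delta_deg`` with its mod-60 and mod-90 remainders, the exclusion flags
    (same start / target / combination / block, both targets on the inner
    ring, both directions cardinal, both trials on the designated
    north-south street) and three distance measures in lattice units:
    ``dist_mean`` (mean of the two start->target vector lengths),
    ``dist_absdiff`` (absolute difference of the two lengths) and
    ``dist_neighborhood`` (mean length of the six vectors connecting the four
    buildings of the pair).
    """
    coords = layout.coords()
    n = len(trials)
    th = trials.direction_deg.to_numpy(dtype=float)
    start = trials.start_id.to_numpy()
    target = trials.target_id.to_numpy()
    block = trials.block.to_numpy()
    ring_by_id = dict(zip(layout.buildings.id.astype(int), layout.buildings.ring))
    inner_target = np.array([ring_by_id[t] == "inner" for t in target])
    cardinal = np.isin(th, CARDINAL_DEG)
    sxy = np.array([coords[s] for s in start])
    txy = np.array([coords[t] for t in target])
    vec = txy - sxy
    length = np.linalg.norm(vec, axis=1)
    on_col = lambda xy: np.abs(xy[:, 0] - ns_street_column_x) < 1e-9
    ns_street = np.isin(th, (90, 270)) & on_col(sxy) & on_col(txy)

    i, j = np.triu_indices(n, k=1)
    delta = wrapped_delta_deg(th[i], th[j])
    pts = np.stack([sxy, txy], axis=1)  # (n, 2, 2)
    quad = np.concatenate([pts[i], pts[j]], axis=1)  # (npairs, 4, 2)
    pair_idx = list(itertools.combinations(range(4), 2))
    neigh = np.mean(
        [np.linalg.norm(quad[:, a] - quad[:, b], axis=1) for a, b in pair_idx], axis=0
    )
    labels = pd.DataFrame(
        {
            "i": i,
            "j": j,
            "delta_deg": np.round(delta).astype(int),
            "rem60": np.round(delta).astype(int) % 60,
            "rem90": np.round(delta).astype(int) % 90,
            "same_start": start[i] == start[j],
            "same_target": target[i] == target[j],
            "same_combo": (start[i] == start[j]) & (target[i] == target[j]),
            "same_block": block[i] == block[j],
            "both_inner_target": inner_target[i] & inner_target[j],
            "both_cardinal": cardinal[i] & cardinal[j],
            "both_ns_street": ns_street[i] & ns_street[j],
            "dist_mean": (length[i] + length[j]) / 2.0,
            "dist_absdiff": np.abs(length[i] - length[j]),
            "dist_neighborhood": neigh,
        }
    )
    return labels
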