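"""Conversion-factor and glandularity tables for breast dosimetry.

The average glandular dose (AGD) in mammography is computed from the incident
air kerma (IAK) through Monte-Carlo-derived conversion factors,

    AGD = IAK * g * c * s,

where ``g(thickness, HVL)`` converts IAK to AGD for a 50 % glandular /
50 % adipose breast, ``c(glandularity, thickness, HVL)`` corrects for a
glandularity different from 50 % (c == 1 at 50 % by construction, > 1 for
fattier and < 1 for denser breasts), and ``s(anode, filter)`` corrects for
x-ray spectra other than Mo/Mo.  A companion age/thickness model supplies the
population ("Dance") glandularity when no individual measurement exists.

This module loads those tables from a long-form CSV, validates them, and
exposes interpolating accessors.  The packaged default table is assembled from
published printed values; users may supply fuller tables in the same format.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy.interpolate import LinearNDInterpolator

logger = logging.getLogger(__name__)

__all__ = [
    "FactorTables",
    "AgeGroupPolicy",
    "DEFAULT_AGE_POLICY",
    "FactorTableError",
    "FactorRangeError",
    "SpectrumLookupError",
    "load_factor_tables",
    "g_factor",
    "c_factor",
    "s_factor",
    "dance_glandularity",
]

#: CSV columns of the long-form factor-table format.
TABLE_COLUMNS = (
    "table_name",
    "glandularity_pct",
    "thickness_mm",
    "hvl_mm_al",
    "anode",
    "filter",
    "age_group",
    "role",
    "value",
)

# Validity ranges of the parametrized factor surfaces (compressed breast
# thickness in mm, half-value layer in mm Al).
THICKNESS_RANGE = (20.0, 110.0)
HVL_RANGE = (0.3, 0.8)


class FactorTableError(ValueError):
    """A factor table failed to load or validate."""


class FactorRangeError(FactorTableError):
    """A query fell outside the validity range of a factor surface."""


class SpectrumLookupError(FactorTableError):
    """An anode/filter combination is not present in the s-factor table."""


@dataclass(frozen=True)
class AgeGroupPolicy:
    """Maps patient age to a tabulated glandularity age group.

    The glandularity model is tabulated only for the 40-49 and 50-64 age
    groups; the default policy substitutes the neighbouring group outside
    that range (< 40 years uses 40-49, >= 65 years uses 50-64).

    ``bounds`` are exclusive upper age bounds, paired one-to-one with
    ``labels``; every age in [0, bounds[-1]) maps to exactly one label.
    """

    bounds: tuple[float, ...] = (50.0, 130.0)
    labels: tuple[str, ...] = ("40-49", "50-64")

    def __post_init__(self) -> None:
        if len(self.bounds) != len(self.labels) or not self.labels:
            raise FactorTableError("age policy needs one bound per label")
        if list(self.bounds) != sorted(set(self.bounds)):
            raise FactorTableError("age policy bounds must be strictly increasing")

    def group_for(self, age: float) -> str:
        if age < 0:
            raise FactorTableError(f"age must be >= 0, got {age}")
        for bound, label in zip(self.bounds, self.labels):
            if age < bound:
                return label
        raise FactorTableError(
            f"age {age} exceeds the policy's last bound {self.bounds[-1]}"
        )


DEFAULT_AGE_POLICY = AgeGroupPolicy()


def _require(condition: bool, message: str) -> None:
    if not condition:
        raise FactorTableError(message)


def _bilinear(t_axis, h_axis, grid, t: float, h: float) -> float:
    """Scalar bilinear interpolation on a small rectangular grid.

    Kept in-house because the hot dosimetry loop evaluates it per exposure
    and generic N-d interpolators dominate the runtime at this call rate.
    Clamps to the grid hull (range checks happen at the query layer).
    """
    i = int(np.searchsorted(t_axis, t)) - 1
    i = min(max(i, 0), len(t_axis) - 2)
    j = int(np.searchsorted(h_axis, h)) - 1
    j = min(max(j, 0), len(h_axis) - 2)
    wt = (t - t_axis[i]) / (t_axis[i + 1] - t_axis[i])
    wh = (h - h_axis[j]) / (h_axis[j + 1] - h_axis[j])
    wt = min(max(wt, 0.0), 1.0)
    wh = min(max(wh, 0.0), 1.0)
    return float(
        (1 - wt) * ((1 - wh) * grid[i, j] + wh * grid[i, j + 1])
        + wt * ((1 - wh) * grid[i + 1, j] + wh * grid[i + 1, j + 1])
    )


def _norm_material(name: str) -> str:
    """Normalize anode/filter material spellings (MOLYBDENUM -> Mo, ...)."""
    aliases = {
        "MOLYBDENUM": "Mo",
        "RHODIUM": "Rh",
        "TUNGSTEN": "W",
        "SILVER": "Ag",
        "ALUMINUM": "Al",
        "ALUMINIUM": "Al",
    }
    key = str(name).strip()
    return aliases.get(key.upper(), key.capitalize() if len(key) <= 2 else key)


class FactorTables:
    """Validated, interpolating container for g, c, s, glandularity and DgN.

    Parameters
    ----------
    frame
        Long-form table with the columns of :data:`TABLE_COLUMNS` (``role`` is
        optional).  Rows are dispatched on ``table_name``:
        ``g`` (thickness, hvl) -> value; ``c`` (glandularity, thickness, hvl)
        -> value; ``s`` (anode, filter) -> value; ``glandularity``
        (age_group, thickness) -> value; ``dgn`` (glandularity, thickness,
        hvl, anode, filter) -> value.
    dgn_table
        Optional normalized-glandular-dose model for the Wu pathway: either a
        callable ``dgn(glandularity, thickness, hvl, anode, filter)`` or a
        scalar (constant DgN).  If the frame carries ``dgn`` rows they are
        used instead.  The default table ships none; see
        :func:`mammodose.dosimetry.dance_equivalent_dgn`.
    """

    def __init__(self, frame: pd.DataFrame, dgn_table=None):
        frame = frame.copy()
        if "role" not in frame.columns:
            frame["role"] = np.nan
        missing = [c for c in TABLE_COLUMNS if c not in frame.columns]
        _require(not missing, f"factor table is missing columns: {missing}")
        _require(len(frame) > 0, "factor table is empty")
        self._frame = frame

        self._build_g(frame[frame.table_name == "g"])
        self._build_c(frame[frame.table_name == "c"])
        self._build_s(frame[frame.table_name == "s"])
        self._build_glandularity(frame[frame.table_name == "glandularity"])
        self._build_dgn(frame[frame.table_name == "dgn"], dgn_table)
        self._clamp_warnings = 0

    # ------------------------------------------------------------------ build

    def _build_g(self, rows: pd.DataFrame) -> None:
        _require(len(rows) > 0, "no 'g' rows in factor table")
        for axis in ("thickness_mm", "hvl_mm_al"):
            _require(rows[axis].notna().all(), f"g table has missing axis values: {axis}")
        _require((rows.value > 0).all(), "non-positive g factor in table")
        pivot = rows.pivot_table(index="thickness_mm", columns="hvl_mm_al", values="value")
        _require(
            not pivot.isna().any().any(),
            "g table is not a complete (thickness, HVL) grid",
        )
        t_axis = pivot.index.to_numpy(dtype=float)
        h_axis = pivot.columns.to_numpy(dtype=float)
        _require(
            t_axis.min() <= THICKNESS_RANGE[0] and t_axis.max() >= THICKNESS_RANGE[1],
            "g grid does not cover the 20-110 mm thickness range (axis: thickness_mm)",
        )
        _require(
            h_axis.min() <= HVL_RANGE[0] and h_axis.max() >= HVL_RANGE[1],
            "g grid does not cover the 0.3-0.8 mm Al HVL range (axis: hvl_mm_al)",
        )
        self.g_grid = pivot
        self._g_axes = (t_axis, h_axis)
        self._g_values = pivot.to_numpy(dtype=float)

    def _build_c(self, rows: pd.DataFrame) -> None:
        """Assemble the c(glandularity, thickness, HVL) surface.

        The surface is structured as one glandularity profile per thickness
        node (piecewise linear in glandularity, end-clamped), blended
        linearly between bracketing thickness nodes.  Profile anchors:

        * the definitional point c(50 %) = 1 (unless the table pins 50 %);
        * anchors with several HVL nodes (the reference-curve rows), linear
          in HVL;
        * single-HVL anchors (isolated printed points), carried to other
          HVLs by scaling with the reference-curve shape at that thickness.

        Linear blending of monotone profiles keeps c strictly decreasing in
        glandularity everywhere, with no overshoot beyond bracketing nodes.
        """
        _require(len(rows) > 0, "no 'c' rows in factor table")
        for axis in ("glandularity_pct", "thickness_mm", "hvl_mm_al"):
            _require(rows[axis].notna().all(), f"c table has missing axis values: {axis}")
        _require((rows.value > 0).all(), "non-positive c factor in table")
        _require(
            rows.glandularity_pct.between(0, 100).all(),
            "c-table glandularity outside [0, 100]",
        )
        self.c_nodes = rows.reset_index(drop=True)

        # Reference curve: the role-less rows (one glandularity per thickness,
        # tabulated across HVL); used for HVL-shape scaling of isolated anchors.
        ref = rows[rows.role.isna()]
        _require(
            len(ref) > 0,
            "c table needs reference rows (role empty) tabulated across HVL",
        )
        ref_pivot = ref.pivot_table(index="thickness_mm", columns="hvl_mm_al", values="value")
        _require(
            not ref_pivot.isna().any().any(),
            "c reference rows do not form a complete (thickness, HVL) grid",
        )
        self._c_ref_axes = (
            ref_pivot.index.to_numpy(float),
            ref_pivot.columns.to_numpy(float),
        )
        self._c_ref_values = ref_pivot.to_numpy(float)

        # Profiles keyed by thickness node.
        profiles: dict[float, list] = {}
        for t_i, sub in rows.groupby("thickness_mm"):
            anchors = []
            for g_a, grp in sub.groupby("glandularity_pct"):
                hs = grp.hvl_mm_al.to_numpy(float)
                vs = grp.value.to_numpy(float)
                order = np.argsort(hs)
                anchors.append((float(g_a), hs[order], vs[order]))
            if not any(np.isclose(a[0], 50.0) for a in anchors):
                anchors.append((50.0, None, None))  # definitional c(50 %) = 1
            profiles[float(t_i)] = sorted(anchors, key=lambda a: a[0])
        self._c_profiles = profiles
        self._c_thickness_nodes = np.array(sorted(profiles))

    @staticmethod
    def _scale_c(points) -> np.ndarray:
        """Normalize (glandularity, thickness, hvl) triples to comparable scales."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        out = np.empty_like(points)
        out[:, 0] = points[:, 0] / 100.0
        out[:, 1] = (points[:, 1] - THICKNESS_RANGE[0]) / (
            THICKNESS_RANGE[1] - THICKNESS_RANGE[0]
        )
        out[:, 2] = (points[:, 2] - HVL_RANGE[0]) / (HVL_RANGE[1] - HVL_RANGE[0])
        return out

    def _c_profile_values(self, t_i: float, hvl: float) -> tuple[np.ndarray, np.ndarray]:
        """Anchor glandularities and c-values of one profile at a given HVL.

        A profile that pins only a single glandularity (the 40 mm node, where
        the reference glandularity is exactly 50 %) borrows its glandularity
        shape from the nearest profiles with two or more anchors, rescaled to
        pass through the pinned value.
        """
        profile = self._c_profiles[t_i]
        if len(profile) == 1:
            return self._degenerate_profile_values(t_i, hvl)
        gs, vs = [], []
        for g_a, hs, vals in profile:
            if hs is None:  # definitional 50 % anchor
                v = 1.0
            elif len(hs) > 1:  # tabulated across HVL
                v = float(np.interp(hvl, hs, vals))
            else:  # isolated point: carry along the reference-curve HVL shape
                ref_here = _bilinear(*self._c_ref_axes, self._c_ref_values, t_i, hvl)
                ref_at_anchor = _bilinear(
                    *self._c_ref_axes, self._c_ref_values, t_i, float(hs[0])
                )
                v = float(vals[0]) * ref_here / ref_at_anchor
            gs.append(g_a)
            vs.append(v)
        return np.asarray(gs), np.asarray(vs)

    def _degenerate_profile_values(self, t_i, hvl) -> tuple[np.ndarray, np.ndarray]:
        g_pin, hs, vals = self._c_profiles[t_i][0]
        v_pin = 1.0 if hs is None else float(np.interp(hvl, hs, vals))
        nodes = self._c_thickness_nodes
        rich = [t for t in nodes if len(self._c_profiles[t]) > 1]
        lower = [t for t in rich if t < t_i]
        upper = [t for t in rich if t > t_i]
        neighbours = []
        if lower and upper:
            lo, hi = max(lower), min(upper)
            w = (hi - t_i) / (hi - lo)
            neighbours = [(lo, w), (hi, 1.0 - w)]
        elif lower or upper:
            neighbours = [(max(lower) if lower else min(upper), 1.0)]
        else:  # pragma: no cover - table with no usable profile at all
            return np.array([g_pin]), np.array([v_pin])
        grids = {t: self._c_profile_values(t, hvl) for t, _ in neighbours}
        union = np.unique(np.concatenate(
            [g for g, _ in grids.values()] + [np.array([g_pin])]
        ))
        blend = np.zeros_like(union)
        for t, w in neighbours:
            gs_n, vs_n = grids[t]
            blend += w * np.interp(union, gs_n, vs_n)
        at_pin = float(np.interp(g_pin, union, blend))
        return union, v_pin * blend / at_pin

    def _build_s(self, rows: pd.DataFrame) -> None:
        _require(len(rows) > 0, "no 's' rows in factor table")
        _require((rows.value > 0).all(), "non-positive s factor in table")
        self.s_table = {
            (_norm_material(a), _norm_material(f)): float(v)
            for a, f, v in zip(rows.anode, rows["filter"], rows.value)
        }
        mo = self.s_table.get(("Mo", "Mo"))
        if mo is not None:
            _require(mo == 1.0, "s(Mo, Mo) must be exactly 1")

    def _build_glandularity(self, rows: pd.DataFrame) -> None:
        _require(len(rows) > 0, "no 'glandularity' rows in factor table")
        _require(
            rows.value.between(0, 100).all(), "glandularity outside [0, 100]"
        )
        self.dance_glandularity_nodes = {}
        for group, sub in rows.groupby("age_group"):
            sub = sub.sort_values("thickness_mm")
            self.dance_glandularity_nodes[str(group)] = (
                sub.thickness_mm.to_numpy(float),
                sub.value.to_numpy(float),
            )

    def _build_dgn(self, rows: pd.DataFrame, dgn_table) -> None:
        if len(rows) > 0:
            _require((rows.value > 0).all(), "non-positive DgN value in table")
            grouped = {}
            for (a, f), sub in rows.groupby(["anode", "filter"]):
                pts = sub[["glandularity_pct", "thickness_mm", "hvl_mm_al"]].to_numpy(float)
                grouped[(_norm_material(a), _norm_material(f))] = LinearNDInterpolator(
                    self._scale_c(pts), sub.value.to_numpy(float)
                )

            def _dgn(gland, thickness, hvl, anode, filt):
                key = (_norm_material(anode), _norm_material(filt))
                if key not in grouped:
                    raise SpectrumLookupError(
                        f"no DgN data for {key}; available: {sorted(grouped)}"
                    )
                val = float(grouped[key](self._scale_c([[gland, thickness, hvl]]))[0])
                if np.isnan(val):
                    raise FactorRangeError(
                        f"DgN query outside table coverage: "
                        f"glandularity={gland}, thickness={thickness}, hvl={hvl}"
                    )
                return val

            self.dgn_table: Callable | None = _dgn
        elif np.isscalar(dgn_table):
            const = float(dgn_table)
            _require(const > 0, "constant DgN must be positive")
            self.dgn_table = lambda gland, thickness, hvl, anode, filt: const
        else:
            self.dgn_table = dgn_table  # callable or None

    # ---------------------------------------------------------------- queries

    def _check_range(self, thickness: float, hvl: float) -> None:
        lo, hi = THICKNESS_RANGE
        if not (lo <= thickness <= hi):
            raise FactorRangeError(
                f"thickness {thickness} mm outside supported range "
                f"[{lo}, {hi}] mm (axis: thickness_mm)"
            )
        lo, hi = HVL_RANGE
        if not (lo <= hvl <= hi):
            raise FactorRangeError(
                f"HVL {hvl} mm Al outside supported range "
                f"[{lo}, {hi}] mm Al (axis: hvl_mm_al)"
            )

    def g(self, thickness: float, hvl: float) -> float:
        """g-factor (IAK -> AGD, 50 % glandularity) at (thickness mm, HVL mm Al)."""
        self._check_range(thickness, hvl)
        return _bilinear(*self._g_axes, self._g_values, thickness, hvl)

    def c(self, glandularity: float, thickness: float, hvl: float) -> float:
        """c-factor (glandularity correction) at (% by weight, mm, mm Al).

        Exact at table nodes; piecewise linear in glandularity within the
        bracketing thickness-node profiles, linear between them, linear in
        HVL.  Glandularity beyond a profile's outermost anchors is clamped
        to the end anchor value (counted in ``clamp_warnings``).
        """
        if not 0.0 <= glandularity <= 100.0:
            raise FactorRangeError(
                f"glandularity {glandularity} outside [0, 100] % by weight"
            )
        self._check_range(thickness, hvl)
        nodes = self._c_thickness_nodes
        t = min(max(thickness, nodes[0]), nodes[-1])
        j = int(np.searchsorted(nodes, t, side="left"))
        j = min(j, len(nodes) - 1)
        if abs(t - nodes[j]) < 1e-9:
            bracket = [(float(nodes[j]), 1.0)]
        else:
            lo, hi = float(nodes[j - 1]), float(nodes[j])
            w = (hi - t) / (hi - lo)
            bracket = [(lo, w), (hi, 1.0 - w)]

        val = 0.0
        clamped = False
        for t_i, weight in bracket:
            gs, vs = self._c_profile_values(t_i, hvl)
            val += weight * float(np.interp(glandularity, gs, vs))
            clamped |= glandularity < gs[0] or glandularity > gs[-1]
        if clamped:
            self._clamp_warnings += 1
            # warn for the first few clamps, then drop to debug to avoid flooding
            log = logger.warning if self._clamp_warnings <= 5 else logger.debug
            log(
                "c-factor glandularity %.3f%% at (%.1f mm, %.3f mm Al) beyond "
                "the outermost tabulated anchors; clamped (clamp #%d)",
                glandularity, thickness, hvl, self._clamp_warnings,
            )
        return val

    @property
    def clamp_warnings(self) -> int:
        """Number of c-factor queries clamped to the glandularity hull."""
        return self._clamp_warnings

    def s(self, anode: str, filt: str) -> float:
        """Spectral correction factor for an anode/filter pair (Mo/Mo = 1)."""
        key = (_norm_material(anode), _norm_material(filt))
        try:
            return self.s_table[key]
        except KeyError:
            raise SpectrumLookupError(
                f"unknown anode/filter pair {key}; supported: {sorted(self.s_table)}"
            ) from None

    def dance_glandularity(
        self,
        age: float,
        thickness: float,
        policy: AgeGroupPolicy | None = None,
    ) -> float:
        """Population glandularity (% by weight) from age and breast thickness.

        The age is mapped to a tabulated group by ``policy`` (default:
        neighbour substitution, < 40 -> 40-49 and >= 65 -> 50-64); the group's
        thickness profile is interpolated linearly and clamped at its ends.
        """
        lo, hi = THICKNESS_RANGE
        if not (lo <= thickness <= hi):
            raise FactorRangeError(
                f"thickness {thickness} mm outside supported range "
                f"[{lo}, {hi}] mm (axis: thickness_mm)"
            )
        policy = policy or DEFAULT_AGE_POLICY
        group = policy.group_for(age)
        if group not in self.dance_glandularity_nodes:
            raise FactorTableError(
                f"no glandularity profile for age group {group!r}; "
                f"available: {sorted(self.dance_glandularity_nodes)}"
            )
        ts, vals = self.dance_glandularity_nodes[group]
        return float(np.clip(np.interp(thickness, ts, vals), 0.0, 100.0))

    def dgn(self, glandularity, thickness, hvl, anode, filt) -> float:
        """Normalized glandular dose (Wu pathway) from the configured table."""
        if self.dgn_table is None:
            raise FactorTableError(
                "no DgN table configured; supply 'dgn' rows, a constant, or a "
                "callable (see mammodose.dosimetry.dance_equivalent_dgn)"
            )
        return float(self.dgn_table(glandularity, thickness, hvl, anode, filt))

    def with_dgn(self, dgn_table) -> "FactorTables":
        """Return a copy of these tables with a different DgN model."""
        return FactorTables(self._frame, dgn_table=dgn_table)

    # ------------------------------------------------------------- summaries

    def cohort_c_pairs(self) -> pd.DataFrame:
        """Paired population/personalized c-values by thickness class.

        Returns the (age_group, thickness, HVL) rows for which the table
        stores both a population-model ("dance") and an individually measured
        ("volpara") c-value, with the percentage dose ratio
        ``round(100 * c_dance / c_volpara)`` that the c-difference induces.
        """
        paired = self.c_nodes[self.c_nodes.role.notna()]
        if paired.empty:
            return pd.DataFrame(
                columns=["age_group", "thickness_mm", "hvl_mm_al",
                         "gland_dance", "gland_volpara",
                         "c_dance", "c_volpara", "ratio_pct"]
            )
        wide = paired.pivot_table(
            index=["age_group", "thickness_mm", "hvl_mm_al"],
            columns="role",
            values=["value", "glandularity_pct"],
        )
        out = pd.DataFrame(
            {
                "gland_dance": wide[("glandularity_pct", "dance")],
                "gland_volpara": wide[("glandularity_pct", "volpara")],
                "c_dance": wide[("value", "dance")],
                "c_volpara": wide[("value", "volpara")],
            }
        ).reset_index()
        out["ratio_pct"] = np.round(100.0 * out.c_dance / out.c_volpara).astype(int)
        return out.sort_values(["age_group", "thickness_mm"]).reset_index(drop=True)


def load_factor_tables(source: str = "default", dgn_table=None) -> FactorTables:
    """Load factor tables from a CSV path or a built-in name.

    ``"default"`` (alias ``"paper-default"``) loads the packaged table
    assembled from published printed values.
    """
    if source in ("default", "paper-default"):
        ref = importlib.resources.files("mammodose.data") / "dance_factors.csv"
        with importlib.resources.as_file(ref) as path:
            frame = pd.read_csv(path)
    else:
        try:
            frame = pd.read_csv(source)
        except FileNotFoundError:
            raise FactorTableError(f"factor table file not found: {source}") from None
        except pd.errors.ParserError as exc:
            raise FactorTableError(f"cannot parse factor table {source}: {exc}") from None
    return FactorTables(frame, dgn_table=dgn_table)


# Thin functional façade mirroring the table accessors.

def g_factor(tables: FactorTables, thickness: float, hvl: float) -> float:
    return tables.g(thickness, hvl)


def c_factor(tables: FactorTables, glandularity: float, thickness: float, hvl: float) -> float:
    return tables.c(glandularity, thickness, hvl)


def s_factor(tables: FactorTables, anode: str, filt: str) -> float:
    return tables.s(anode, filt)


def dance_glandularity(
    tables: FactorTables, age: float, thickness: float,
    policy: AgeGroupPolicy | None = None,
) -> float:
    return tables.dance_glandularity(age, thickness, policy=policy)
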