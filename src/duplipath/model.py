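"""Environmentally regulated developmental outcomes in pathways with duplicated genes.

``duplipath`` simulates a two-tier gene-regulatory cascade in which each tier
may carry several duplicated copies (paralogs) of a gene.  Every copy has a
unimodal activity curve over each of two environmental factors (an optimum
plus decay rates below/above it, on a 1-20 environmental scale), the product
of the two curves giving the copy's environmental weight.  Upstream activity
feeds the downstream tier through a saturating (logistic) link, downstream
activity feeds the final developmental/physiological outcome through a second
logistic link, and the resulting outcome probability ``P(e1, e2)`` is
evaluated on a grid of environmental conditions.  The surface can then be
analysed for local peaks (how many distinct environmental combinations permit
the outcome), environmental breadth around the peak (niche precision), total
probability mass, and the match between surface peaks and individual gene
optima.

The module is laid out in the order the computation runs:

1.  elementary functions -- environmental response curves and logistic links;
2.  pathway composition  -- copies + links + wiring -> outcome surface;
3.  surface analysis     -- peaks, breadth, mass, peak/optimum matching,
                            parameter sweeps;
4.  figure registry      -- ready-made pathway configurations for the
                            published figure panels, with their qualitative
                            expectations encoded as machine checks;
5.  configuration & I/O  -- YAML/JSON run configs, CSV/JSON serialization,
                            optional heat-map rendering.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import os
import re
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage
from scipy.special import expit

logger = logging.getLogger("duplipath")

#: Environmental factors are scaled from 1 to 20; the default evaluation grid
#: is the integer lattice on that range.
ENV_MIN = 1
ENV_MAX = 20

#: Default threshold above the surface floor for a local maximum to count as
#: a peak.  Suppresses floor-level ripple without masking any of the
#: registered panels' secondary peaks, which all rise far above it.
DEFAULT_MIN_PROMINENCE = 0.05


class ParameterError(ValueError):
    """A model parameter violates its domain (e.g. a negative decay rate)."""


class WiringError(ParameterError):
    """Pathway wiring is inconsistent with the copy counts."""


class ConfigError(ValueError):
    """A run-configuration file could not be used.

    ``kind`` distinguishes the failure mode: ``"parse"`` (not valid
    YAML/JSON), ``"schema"`` (unknown or missing keys, wrong types) or
    ``"value"`` (well-formed but out-of-domain parameter values).
    """

    def __init__(self, message: str, kind: str = "schema"):
        super().__init__(message)
        self.kind = kind


class UnknownFigureError(KeyError):
    """Requested figure panel id is not in the registry."""


# ---------------------------------------------------------------------------
# 1. Elementary functions: environmental responses and logistic links
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EnvResponse:
    """Unimodal activity curve of one gene copy over one environmental factor.

    The activity equals 1 at ``optimum`` and decays as a (possibly
    asymmetric) Gaussian away from it:

    .. math::

        f(e) = \\exp(-r \\, (e - \\mathrm{opt})^2), \\qquad
        r = \\begin{cases} \\text{rate\\_below} & e < \\mathrm{opt} \\\\
                           \\text{rate\\_above} & e \\ge \\mathrm{opt}
            \\end{cases}

    Parameters
    ----------
    optimum:
        Environmental value of peak activity, in units of the 1-20 scale.
    rate_below, rate_above:
        Non-negative decay rates (per squared environmental unit) below and
        above the optimum.  Equal rates give a symmetric thermal-performance
        style curve; ``rate_above = 0`` gives a monotone non-decreasing
        (photoperiod-style) response; both zero gives the constant function 1
        (an environmentally insensitive gene).
    """

    optimum: float
    rate_below: float = 0.0
    rate_above: float = 0.0

    def __post_init__(self):
        if self.rate_below < 0 or self.rate_above < 0:
            raise ParameterError(
                f"decay rates must be non-negative, got "
                f"rate_below={self.rate_below}, rate_above={self.rate_above}"
            )

    def __call__(self, e):
        return env_response(e, self)

    @property
    def insensitive(self) -> bool:
        """True when the curve is the constant function 1."""
        return self.rate_below == 0 and self.rate_above == 0


def env_response(e, r: EnvResponse):
    """Activity probability of one copy at environmental value ``e``.

    The boundary ``e == optimum`` uses ``rate_above`` (half-open convention,
    irrelevant for symmetric curves).  Accepts scalars or arrays.
    """
    e = np.asarray(e, dtype=float)
    rate = np.where(e < r.optimum, r.rate_below, r.rate_above)
    out = np.exp(-rate * (e - r.optimum) ** 2)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class SigmoidLink:
    """Saturating regulatory transfer function between pathway tiers.

    .. math:: \\sigma(x) = \\frac{1}{1 + \\exp(\\mathrm{intercept}
              - \\mathrm{slope}\\cdot x)}

    ``slope`` is the dimensionless gain per unit of summed activity; the
    inflection of the canonical form sits at ``intercept / slope``.  Output
    is strictly inside (0, 1), so every outcome surface has a nonzero floor
    ``sigma(0)``.
    """

    intercept: float
    slope: float

    def __post_init__(self):
        if self.slope < 0:
            raise ParameterError(f"sigmoid slope must be non-negative, got {self.slope}")

    def __call__(self, x):
        return sigmoid_link(x, self)

    @property
    def inflection(self) -> float:
        if self.slope == 0:
            raise ParameterError("a zero-slope link has no inflection point")
        return self.intercept / self.slope

    @property
    def floor(self) -> float:
        """Output at zero input."""
        return float(expit(-self.intercept))


def sigmoid_link(x, s: SigmoidLink):
    """Logistic transfer ``1 / (1 + exp(intercept - slope*x))``.

    Strictly increasing in ``x`` for positive slope; numerically safe for
    arbitrarily large ``|intercept - slope*x|``.
    """
    x = np.asarray(x, dtype=float)
    out = expit(s.slope * x - s.intercept)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class GeneCopyParams:
    """One gene copy: sensitivity curves for the two environmental factors."""

    response_e1: EnvResponse
    response_e2: EnvResponse
    label: str = ""

    @property
    def optima(self) -> tuple[float, float]:
        return (self.response_e1.optimum, self.response_e2.optimum)


def env_weight(e1, e2, g: GeneCopyParams):
    """Environmental weight of a copy: product of its two response curves.

    Lies in [0, 1] and equals 1 exactly at the copy's optimum pair when both
    rates are positive (the "star" condition of the figure panels).
    """
    return env_response(e1, g.response_e1) * env_response(e2, g.response_e2)


# ---------------------------------------------------------------------------
# 2. Pathway composition and surface evaluation
# ---------------------------------------------------------------------------

#: Wiring is either the string ``"pooled"`` (each downstream copy receives
#: the summed activity of all upstream copies), ``"independent"`` (copy i
#: feeds copy i; requires equal copy counts) or an explicit mapping from
#: 1-based downstream index to a set of 1-based upstream indices.
Wiring = "str | Mapping[int, frozenset[int]]"


def _canonical_wiring(wiring, n_up: int, n_down: int):
    if isinstance(wiring, str):
        if wiring not in ("pooled", "independent"):
            raise WiringError(f"unknown wiring {wiring!r}")
        if wiring == "independent" and n_up != n_down:
            raise WiringError(
                f"independent wiring requires equal copy counts, got "
                f"{n_up} upstream vs {n_down} downstream"
            )
        return wiring
    try:
        items = {int(k): frozenset(int(i) for i in v) for k, v in dict(wiring).items()}
    except (TypeError, ValueError) as exc:
        raise WiringError(f"explicit wiring map is malformed: {wiring!r}") from exc
    if set(items) != set(range(1, n_down + 1)):
        raise WiringError(
            f"explicit wiring must map every downstream index 1..{n_down}, "
            f"got keys {sorted(items)}"
        )
    for j, ups in items.items():
        bad = [i for i in ups if not 1 <= i <= n_up]
        if bad:
            raise WiringError(
                f"downstream copy {j} references invalid upstream indices {bad}"
            )
    return items


@dataclass(frozen=True)
class PathwayConfig:
    """Full pathway architecture.

    ``upstream``/``downstream`` are ordered copy lists, ``link_up_down`` is
    the upstream->downstream logistic (the delta link), ``link_down_outcome``
    the downstream->outcome logistic (the gamma link).
    """

    upstream: tuple[GeneCopyParams, ...]
    downstream: tuple[GeneCopyParams, ...]
    link_up_down: SigmoidLink
    link_down_outcome: SigmoidLink
    wiring: object = "pooled"

    def __post_init__(self):
        object.__setattr__(self, "upstream", tuple(self.upstream))
        object.__setattr__(self, "downstream", tuple(self.downstream))
        if not self.upstream or not self.downstream:
            raise ParameterError("at least one upstream and one downstream copy required")
        object.__setattr__(
            self,
            "wiring",
            _canonical_wiring(self.wiring, len(self.upstream), len(self.downstream)),
        )

    @property
    def n_upstream(self) -> int:
        return len(self.upstream)

    @property
    def n_downstream(self) -> int:
        return len(self.downstream)

    @property
    def floor(self) -> float:
        """Surface floor: outcome probability when all downstream activity is 0."""
        return self.link_down_outcome.floor


@dataclass(frozen=True)
class EnvGrid:
    """Ordered evaluation values for the two environmental factors."""

    e1_values: np.ndarray
    e2_values: np.ndarray

    def __post_init__(self):
        for name in ("e1_values", "e2_values"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.ndim != 1 or v.size == 0:
                raise ParameterError(f"{name} must be a non-empty 1-D sequence")
            if v.size > 1 and not np.all(np.diff(v) > 0):
                raise ParameterError(f"{name} must be strictly increasing")
            v.setflags(write=False)
            object.__setattr__(self, name, v)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.e1_values.size, self.e2_values.size)

    @property
    def n_cells(self) -> int:
        return self.e1_values.size * self.e2_values.size

    def index_of(self, e1: float, e2: float) -> tuple[int, int]:
        """Array indices of a cell given in environmental units."""
        i = np.flatnonzero(np.isclose(self.e1_values, e1))
        j = np.flatnonzero(np.isclose(self.e2_values, e2))
        if i.size == 0 or j.size == 0:
            raise KeyError(f"cell ({e1}, {e2}) not on the grid")
        return int(i[0]), int(j[0])

    def __eq__(self, other):
        return (
            isinstance(other, EnvGrid)
            and np.array_equal(self.e1_values, other.e1_values)
            and np.array_equal(self.e2_values, other.e2_values)
        )

    def __hash__(self):  # frozen dataclass with arrays: hash on tuples
        return hash((tuple(self.e1_values), tuple(self.e2_values)))


def default_grid(step: float = 1.0) -> EnvGrid:
    """Integer lattice 1..20 on both axes (or a finer regular lattice)."""
    vals = np.arange(ENV_MIN, ENV_MAX + step / 2, step, dtype=float)
    return EnvGrid(vals, vals.copy())


def upstream_activities(cfg: PathwayConfig, e1, e2) -> np.ndarray:
    """Per-upstream-copy activity U_i = env_weight(e1, e2, copy_i).

    Returns an array whose leading axis indexes upstream copies; trailing
    axes follow the broadcast shape of ``e1``/``e2``.
    """
    return np.stack([np.asarray(env_weight(e1, e2, g), dtype=float) for g in cfg.upstream])


def downstream_inputs(cfg: PathwayConfig, U: np.ndarray) -> np.ndarray:
    """Regulatory input to each downstream copy, per the wiring.

    pooled: every downstream copy receives sum_i U_i; independent: copy j
    receives U_j; explicit map: copy j receives the sum over its mapped
    upstream indices.
    """
    U = np.asarray(U, dtype=float)
    if U.shape[0] != cfg.n_upstream:
        raise WiringError(
            f"expected {cfg.n_upstream} upstream activities, got {U.shape[0]}"
        )
    if cfg.wiring == "pooled":
        total = U.sum(axis=0)
        return np.stack([total] * cfg.n_downstream)
    if cfg.wiring == "independent":
        return U.copy()
    rows = []
    for j in range(1, cfg.n_downstream + 1):
        idx = sorted(cfg.wiring[j])
        if idx:
            rows.append(U[[i - 1 for i in idx]].sum(axis=0))
        else:
            rows.append(np.zeros(U.shape[1:]))
    return np.stack(rows)


def downstream_activities(cfg: PathwayConfig, inputs: np.ndarray, e1, e2) -> np.ndarray:
    """Per-downstream-copy activity D_j = sigma_delta(input_j) * env_weight_j."""
    inputs = np.asarray(inputs, dtype=float)
    return np.stack(
        [
            sigmoid_link(inputs[j], cfg.link_up_down)
            * np.asarray(env_weight(e1, e2, g), dtype=float)
            for j, g in enumerate(cfg.downstream)
        ]
    )


def outcome_probability(cfg: PathwayConfig, e1, e2):
    """Outcome probability P(e1, e2) = sigma_gamma(sum_j D_j).

    Equals the chained composition upstream_activities -> downstream_inputs
    -> downstream_activities -> outcome link; scalar in, scalar out.
    """
    U = upstream_activities(cfg, e1, e2)
    D = downstream_activities(cfg, downstream_inputs(cfg, U), e1, e2)
    return sigmoid_link(D.sum(axis=0), cfg.link_down_outcome)


@dataclass(frozen=True)
class OutcomeSurface:
    """Outcome probability and per-copy activities on an environment grid.

    ``P`` has shape ``grid.shape`` (axis 0 = factor 1); ``U`` and ``D`` carry
    a leading copy axis.  Deterministic: identical configs and grids give
    bit-identical arrays.
    """

    grid: EnvGrid
    P: np.ndarray
    U: np.ndarray
    D: np.ndarray
    config: PathwayConfig

    def value_at(self, e1: float, e2: float) -> float:
        i, j = self.grid.index_of(e1, e2)
        return float(self.P[i, j])

    def argmax_cell(self) -> tuple[float, float]:
        """Environment values of the global maximum (lexicographically first)."""
        i, j = np.unravel_index(int(np.argmax(self.P)), self.P.shape)
        return (float(self.grid.e1_values[i]), float(self.grid.e2_values[j]))

    @property
    def floor(self) -> float:
        return self.config.floor


def evaluate_surface(cfg: PathwayConfig, grid: EnvGrid | None = None) -> OutcomeSurface:
    """Evaluate the outcome surface (and per-copy activities) on a grid."""
    grid = grid if grid is not None else default_grid()
    E1, E2 = np.meshgrid(grid.e1_values, grid.e2_values, indexing="ij")
    U = upstream_activities(cfg, E1, E2)
    D = downstream_activities(cfg, downstream_inputs(cfg, U), E1, E2)
    P = sigmoid_link(D.sum(axis=0), cfg.link_down_outcome)
    for name, a in (("P", P), ("U", U), ("D", D)):
        a.setflags(write=False)
    return OutcomeSurface(grid=grid, P=P, U=U, D=D, config=cfg)


# ---------------------------------------------------------------------------
# 3. Surface analysis: peaks, breadth, mass, matching, sweeps
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PeakSet:
    """Local maxima of an outcome surface.

    ``peaks`` holds ``(e1, e2, P)`` tuples sorted by descending P, ties
    broken by ascending (e1, e2).  Every peak exceeds
    ``floor + min_prominence``.
    """

    peaks: tuple[tuple[float, float, float], ...]
    floor: float
    min_prominence: float

    def __len__(self):
        return len(self.peaks)

    @property
    def cells(self) -> tuple[tuple[float, float], ...]:
        return tuple((p[0], p[1]) for p in self.peaks)


def find_local_maxima(
    surface: OutcomeSurface, min_prominence: float = DEFAULT_MIN_PROMINENCE
) -> PeakSet:
    """Detect peaks: cells whose P >= all existing 8-neighbours.

    Connected plateaus of equal value merge into one peak reported at the
    lexicographically smallest cell; candidates not exceeding
    ``floor + min_prominence`` are discarded.  A constant surface therefore
    yields exactly one plateau peak (or none, for positive prominence).
    """
    P = surface.P
    neigh = ndimage.maximum_filter(P, size=3, mode="constant", cval=-np.inf)
    candidates = P >= neigh  # >= because the filter window includes the cell
    labels, n = ndimage.label(candidates, structure=np.ones((3, 3), dtype=int))
    floor = surface.floor
    found = []
    for lab in range(1, n + 1):
        cells = np.argwhere(labels == lab)
        # adjacent candidate cells necessarily share one value: a plateau
        i, j = min(map(tuple, cells))
        value = float(P[i, j])
        if value > floor + min_prominence:
            found.append(
                (float(surface.grid.e1_values[i]), float(surface.grid.e2_values[j]), value)
            )
    found.sort(key=lambda t: (-t[2], t[0], t[1]))
    return PeakSet(peaks=tuple(found), floor=floor, min_prominence=min_prominence)


@dataclass(frozen=True)
class SurfaceMetrics:
    """Scalar summaries of an outcome surface.

    All breadth thresholds are measured above the surface floor (the gamma
    link's output at zero downstream activity), because that floor is a
    structural baseline, not signal.
    """

    n_peaks: int
    peak_cells: tuple[tuple[float, float], ...]
    max_P: float
    argmax: tuple[float, float]
    half_max_area: int
    axis_halfwidths: tuple[int, int]
    total_mass: float
    n_cells: int
    floor: float
    flat: bool
    value_at: dict[tuple[float, float], float] = field(default_factory=dict)
    peak_optimum_distances: tuple[dict, ...] = ()


def breadth_metrics(
    surface: OutcomeSurface,
    min_prominence: float = DEFAULT_MIN_PROMINENCE,
    query_cells: Sequence[tuple[float, float]] = (),
) -> SurfaceMetrics:
    """Peaks, half-max breadth, axis half-widths and total mass of a surface.

    ``half_max_area`` counts cells with ``P >= floor + (max - floor)/2``;
    ``axis_halfwidths`` count such cells on the grid lines through the global
    peak.  A (numerically) flat surface is flagged and assigned the full grid
    as its half-max area.  ``total_mass`` is the plain cell sum of P.
    """
    P = surface.P
    floor = surface.floor
    peaks = find_local_maxima(surface, min_prominence)
    i, j = np.unravel_index(int(np.argmax(P)), P.shape)
    flat = bool(P.max() - P.min() < 1e-12)
    if flat:
        area = P.size
        hw = (P.shape[0], P.shape[1])
        logger.warning("degenerate flat surface: half-max area set to full grid")
    else:
        level = floor + (P.max() - floor) / 2.0
        area = int((P >= level).sum())
        hw = (int((P[:, j] >= level).sum()), int((P[i, :] >= level).sum()))
    return SurfaceMetrics(
        n_peaks=len(peaks),
        peak_cells=peaks.cells,
        max_P=float(P.max()),
        argmax=surface.argmax_cell(),
        half_max_area=area,
        axis_halfwidths=hw,
        total_mass=float(P.sum()),
        n_cells=P.size,
        floor=floor,
        flat=flat,
        value_at={(float(a), float(b)): surface.value_at(a, b) for a, b in query_cells},
        peak_optimum_distances=tuple(
            _peak_optimum_records(peaks, surface.config)
        ),
    )


def _peak_optimum_records(peaks: PeakSet, cfg: PathwayConfig) -> list[dict]:
    records = []
    for pe1, pe2, pval in peaks.peaks:
        for tier, copies in (("upstream", cfg.upstream), ("downstream", cfg.downstream)):
            for k, g in enumerate(copies, start=1):
                o1, o2 = g.optima
                records.append(
                    {
                        "peak_e1": pe1,
                        "peak_e2": pe2,
                        "peak_P": pval,
                        "tier": tier,
                        "copy": k,
                        "label": g.label,
                        "opt_e1": o1,
                        "opt_e2": o2,
                        "distance": math.hypot(pe1 - o1, pe2 - o2),
                    }
                )
    return records


def peak_optimum_match(peaks: PeakSet, cfg: PathwayConfig) -> pd.DataFrame:
    """Euclidean distance (environment units) from every peak to every copy optimum.

    One row per peak x tier x copy; empty peak set gives an empty table.
    """
    cols = [
        "peak_e1", "peak_e2", "peak_P", "tier", "copy", "label",
        "opt_e1", "opt_e2", "distance",
    ]
    return pd.DataFrame(_peak_optimum_records(peaks, cfg), columns=cols)


@dataclass(frozen=True)
class SurfaceComparison:
    """Ordered metric differences between two surfaces (a minus b)."""

    delta_total_mass: float
    delta_max: float
    delta_value_at: dict[tuple[float, float], float]
    peak_matching: tuple[dict, ...]


def compare_surfaces(
    a: OutcomeSurface,
    b: OutcomeSurface,
    query_cells: Sequence[tuple[float, float]] = (),
    min_prominence: float = DEFAULT_MIN_PROMINENCE,
) -> SurfaceComparison:
    """Compare two surfaces on the same grid (all deltas are a minus b)."""
    if a.grid != b.grid:
        raise ParameterError("surfaces were evaluated on different grids")
    pa, pb = find_local_maxima(a, min_prominence), find_local_maxima(b, min_prominence)
    matching = []
    for pe1, pe2, pv in pa.peaks:
        if pb.peaks:
            qe1, qe2, qv = min(
                pb.peaks, key=lambda q: math.hypot(q[0] - pe1, q[1] - pe2)
            )
            matching.append(
                {
                    "a_peak": (pe1, pe2, pv),
                    "b_peak": (qe1, qe2, qv),
                    "distance": math.hypot(qe1 - pe1, qe2 - pe2),
                }
            )
        else:
            matching.append({"a_peak": (pe1, pe2, pv), "b_peak": None, "distance": None})
    return SurfaceComparison(
        delta_total_mass=float(a.P.sum() - b.P.sum()),
        delta_max=float(a.P.max() - b.P.max()),
        delta_value_at={
            (float(c1), float(c2)): a.value_at(c1, c2) - b.value_at(c1, c2)
            for c1, c2 in query_cells
        },
        peak_matching=tuple(matching),
    )


_PATH_TOKEN = re.compile(r"^([A-Za-z_][A-Za-z_0-9]*)(?:\[(\d+)\])?$")


def _replace_by_path(obj, tokens: list[tuple[str, int | None]], value):
    (name, idx), rest = tokens[0], tokens[1:]
    if not dataclasses.is_dataclass(obj) or name not in {f.name for f in dataclasses.fields(obj)}:
        raise KeyError(f"unknown parameter field {name!r} on {type(obj).__name__}")
    child = getattr(obj, name)
    if idx is not None:
        seq = list(child)
        if not 0 <= idx < len(seq):
            raise KeyError(f"index {idx} out of range for {name!r}")
        seq[idx] = value if not rest else _replace_by_path(seq[idx], rest, value)
        new_child = tuple(seq)
    else:
        new_child = value if not rest else _replace_by_path(child, rest, value)
    return dataclasses.replace(obj, **{name: new_child})


def set_parameter(cfg: PathwayConfig, parameter_path: str, value) -> PathwayConfig:
    """Return a copy of ``cfg`` with one scalar field replaced.

    ``parameter_path`` is a dotted path with optional 0-based indices, e.g.
    ``"link_down_outcome.slope"`` or ``"upstream[0].response_e1.optimum"``.
    """
    tokens = []
    for part in parameter_path.split("."):
        m = _PATH_TOKEN.match(part)
        if not m:
            raise KeyError(f"malformed parameter path component {part!r}")
        tokens.append((m.group(1), int(m.group(2)) if m.group(2) else None))
    return _replace_by_path(cfg, tokens, value)


def parameter_sweep(
    base_cfg: PathwayConfig,
    parameter_path: str,
    values: Iterable[float],
    grid: EnvGrid | None = None,
    min_prominence: float = DEFAULT_MIN_PROMINENCE,
) -> pd.DataFrame:
    """Surface metrics for each value of one scalar config parameter.

    Deterministic; ``base_cfg`` is never modified (configs are immutable).
    One row per value with the headline ``SurfaceMetrics`` fields.
    """
    rows = []
    for v in values:
        cfg = set_parameter(base_cfg, parameter_path, float(v))
        m = breadth_metrics(evaluate_surface(cfg, grid), min_prominence)
        rows.append(
            {
                "value": float(v),
                "n_peaks": m.n_peaks,
                "max_P": m.max_P,
                "argmax_e1": m.argmax[0],
                "argmax_e2": m.argmax[1],
                "half_max_area": m.half_max_area,
                "halfwidth_e1": m.axis_halfwidths[0],
                "halfwidth_e2": m.axis_halfwidths[1],
                "total_mass": m.total_mass,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# 4. Figure registry: the published panel configurations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FigureConfig:
    """A registered figure-panel configuration.

    ``expected_qualitative`` encodes the published qualitative claims about
    the panel as machine-checkable expectations; recognised keys:

    - ``argmax``: the global maximum must sit at this (e1, e2) cell;
    - ``argmax_not``: the global maximum must *not* sit at this cell;
    - ``n_peaks``: exact local-maximum count at the default prominence;
    - ``peak_cells``: the exact set of peak cells.
    """

    id: str
    config: PathwayConfig
    notes: str
    expected_qualitative: Mapping[str, object] = field(default_factory=dict)


def _sym(opt: float, rate: float) -> EnvResponse:
    return EnvResponse(optimum=opt, rate_below=rate, rate_above=rate)


def _copy(o1, o2, r1=0.01, r2=0.01, label="") -> GeneCopyParams:
    return GeneCopyParams(_sym(o1, r1), _sym(o2, r2), label=label)


_LINK_SHALLOW = SigmoidLink(intercept=1, slope=2)   # the (1, 2) pairing
_LINK_STEEP = SigmoidLink(intercept=5, slope=7)     # the (5, 7) pairing

# Insensitive tiers keep the shared optimum pair (10, 12) as a bookkeeping
# anchor; with zero rates the optimum never enters the computation.
_FLAT = _copy(10, 12, 0, 0, label="insensitive")


def _panel(fid, up, down, link_ud, link_do, wiring, notes, expected):
    cfg = PathwayConfig(
        upstream=tuple(up),
        downstream=tuple(down),
        link_up_down=link_ud,
        link_down_outcome=link_do,
        wiring=wiring,
    )
    return FigureConfig(id=fid, config=cfg, notes=notes, expected_qualitative=expected)


def _build_registry() -> dict[str, FigureConfig]:
    L, S = _LINK_SHALLOW, _LINK_STEEP
    up = _copy(10, 12, label="upstream")
    dn = _copy(10, 12, label="downstream")
    reg = [
        # --- upstream vs downstream sensitivity, no diversification -------
        _panel("2A", [up], [_FLAT], L, L, "pooled",
               "Only the upstream gene environmentally sensitive; optima (10, 12).",
               {"argmax": (10, 12), "n_peaks": 1}),
        _panel("2B", [_FLAT], [dn], L, L, "pooled",
               "Only the downstream gene environmentally sensitive; optima (10, 12).",
               {"argmax": (10, 12), "n_peaks": 1}),
        _panel("2C",
               [_copy(10, 12, 0.01, 0, label="upstream e1-only")],
               [_copy(10, 12, 0, 0.01, label="downstream e2-only")],
               L, L, "pooled",
               "Upstream sensitive to factor 1 only (opt 10), downstream to factor 2 only (opt 12).",
               {"argmax": (10, 12)}),
        _panel("2D", [up], [dn], L, L, "pooled",
               "Both tiers identically sensitive; optima (10, 12).",
               {"argmax": (10, 12), "n_peaks": 1}),
        _panel("2E",
               [_copy(10, 12, 0.01, 0, label="upstream e1-only")],
               [_copy(10, 12, 0, 0.01, label="downstream e2-only")],
               S, L, "pooled",
               "As 2C but with the steeper (5, 7) upstream-to-downstream link.",
               {"argmax": (10, 12)}),
        # --- compensatory optima vs an adaptive optimum at (10, 12) -------
        _panel("3A", [up], [dn], L, L, "pooled",
               "Both tiers peak at the adaptive optimum (10, 12).",
               {"argmax": (10, 12)}),
        _panel("3B", [up], [_copy(5, 8, label="downstream")], L, L, "pooled",
               "Downstream optimum displaced to (5, 8); upstream still at (10, 12).",
               {"argmax_not": (10, 12)}),
        _panel("3C",
               [_copy(15, 16, label="upstream")],
               [_copy(5, 8, label="downstream")],
               L, L, "pooled",
               "Compensatory displacement: upstream (15, 16), downstream (5, 8).",
               {"argmax": (10, 12)}),
        # --- diversification of gene copies (steep delta, shallow gamma) --
        _panel("4A",
               [_copy(10, 8, label="up1"), _copy(10, 16, label="up2")],
               [_copy(5, 12, label="down1"), _copy(15, 12, label="down2")],
               S, L, "independent",
               "Upstream copies divergent in factor 2, downstream copies in factor 1.",
               {}),
        _panel("4B",
               [_copy(5, 8, label="up1"), _copy(15, 16, label="up2")],
               [_copy(10, 12, label="down1"), _copy(10, 12, label="down2")],
               S, L, "independent",
               "Upstream copies divergent in both factors; downstream copies undiverged.",
               {"n_peaks": 2}),
        _panel("4C",
               [_copy(10, 12, label="up1"), _copy(10, 12, label="up2")],
               [_copy(5, 8, label="down1"), _copy(15, 16, label="down2")],
               S, L, "independent",
               "Downstream copies divergent in both factors; upstream copies undiverged.",
               {"n_peaks": 1}),
        _panel("4D",
               [_copy(5, 8, label="up1"), _copy(15, 16, label="up2")],
               [_copy(5, 8, label="down1"), _copy(15, 16, label="down2")],
               S, L, "independent",
               "Both tiers identically divergent: (5, 8) and (15, 16).",
               {"n_peaks": 2, "peak_cells": ((5, 8), (15, 16))}),
        # --- pooled vs independent regulation ------------------------------
        _panel("5A",
               [_copy(5, 8, label="up1"), _copy(15, 16, label="up2")],
               [_copy(5, 8, label="down1"), _copy(15, 16, label="down2")],
               S, L, "pooled",
               "Identically divergent copies under pooled regulation.",
               {}),
        _panel("5B",
               [_copy(5, 8, label="up1"), _copy(15, 16, label="up2")],
               [_copy(5, 8, label="down1"), _copy(15, 16, label="down2")],
               S, L, "independent",
               "Identically divergent copies under independent regulation.",
               {"n_peaks": 2, "peak_cells": ((5, 8), (15, 16))}),
        _panel("5C",
               [_copy(5, 8, label="up1"), _copy(15, 16, label="up2")],
               [_copy(15, 16, label="down1"), _copy(5, 8, label="down2")],
               S, L, "pooled",
               "Mismatched pairings (up1 (5,8) with down1 (15,16)) under pooled regulation.",
               {}),
        _panel("5D",
               [_copy(5, 8, label="up1"), _copy(15, 16, label="up2")],
               [_copy(15, 16, label="down1"), _copy(5, 8, label="down2")],
               S, L, "independent",
               "Mismatched pairings under independent regulation.",
               {}),
    ]
    return {p.id: p for p in reg}


_REGISTRY = _build_registry()

FIGURE_IDS = tuple(sorted(_REGISTRY))


def get_figure_config(fig_id: str, wiring=None) -> FigureConfig:
    """Fully resolved configuration of a registered figure panel.

    ``wiring`` overrides the registered wiring mode (e.g. to render the
    multi-copy panels under pooled instead of independent regulation).
    """
    try:
        fc = _REGISTRY[fig_id]
    except KeyError:
        raise UnknownFigureError(
            f"unknown figure id {fig_id!r}; known ids: {', '.join(FIGURE_IDS)}"
        ) from None
    if wiring is not None and wiring != fc.config.wiring:
        fc = dataclasses.replace(
            fc,
            config=dataclasses.replace(fc.config, wiring=wiring),
            notes=fc.notes + f" (wiring overridden to {wiring!r})",
        )
    return fc


def check_expected(surface: OutcomeSurface, expected: Mapping[str, object],
                   min_prominence: float = DEFAULT_MIN_PROMINENCE) -> list[dict]:
    """Evaluate a panel's qualitative expectations against its surface."""
    report = []
    peaks = find_local_maxima(surface, min_prominence)
    argmax = surface.argmax_cell()
    for key, want in expected.items():
        if key == "argmax":
            got, ok = argmax, argmax == tuple(want)
        elif key == "argmax_not":
            got, ok = argmax, argmax != tuple(want)
        elif key == "n_peaks":
            got, ok = len(peaks), len(peaks) == want
        elif key == "peak_cells":
            got = peaks.cells
            ok = set(got) == {tuple(c) for c in want}
        else:
            raise KeyError(f"unknown expectation key {key!r}")
        report.append({"claim": key, "expected": want, "observed": got, "passed": ok})
    return report


@dataclass(frozen=True)
class FigureRun:
    """Everything produced by :func:`run_figure` for one panel."""

    figure: FigureConfig
    surface: OutcomeSurface
    metrics: SurfaceMetrics
    peaks: PeakSet
    claims: tuple[dict, ...]
    paths: tuple[str, ...]

    @property
    def all_claims_pass(self) -> bool:
        return all(c["passed"] for c in self.claims)


def run_figure(
    fig_id: str,
    grid: EnvGrid | None = None,
    output_dir=None,
    formats: Sequence[str] = ("csv", "json"),
    wiring=None,
    min_prominence: float = DEFAULT_MIN_PROMINENCE,
    render: bool = False,
) -> FigureRun:
    """Evaluate, analyse and (optionally) serialize one registered panel."""
    fc = get_figure_config(fig_id, wiring=wiring)
    surface = evaluate_surface(fc.config, grid)
    metrics = breadth_metrics(surface, min_prominence)
    peaks = find_local_maxima(surface, min_prominence)
    claims = tuple(check_expected(surface, fc.expected_qualitative, min_prominence))
    paths: tuple[str, ...] = ()
    if output_dir is not None:
        paths = tuple(
            write_surface(
                surface, output_dir, formats=formats, metrics=metrics, peaks=peaks,
                stem=f"figure_{fig_id}", render=render,
            ).values()
        )
    for c in claims:
        if not c["passed"]:
            logger.warning(
                "panel %s: claim %r failed (expected %r, observed %r)",
                fig_id, c["claim"], c["expected"], c["observed"],
            )
    return FigureRun(fc, surface, metrics, peaks, claims, paths)


# ---------------------------------------------------------------------------
# 5. Configuration files, serialization, rendering
# ---------------------------------------------------------------------------

from pydantic import BaseModel, ConfigDict, Field, ValidationError  # noqa: E402


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class _ResponseModel(_Strict):
    optimum: float
    rate_below: float = Field(default=0.0, ge=0)
    rate_above: float = Field(default=0.0, ge=0)


class _CopyModel(_Strict):
    response_e1: _ResponseModel
    response_e2: _ResponseModel
    label: str = ""


class _LinkModel(_Strict):
    intercept: float
    slope: float = Field(ge=0)


class _PathwayModel(_Strict):
    upstream: list[_CopyModel] = Field(min_length=1)
    downstream: list[_CopyModel] = Field(min_length=1)
    link_up_down: _LinkModel
    link_down_outcome: _LinkModel
    wiring: "str | dict[int, list[int]]" = "pooled"


class _GridModel(_Strict):
    e1_min: float = ENV_MIN
    e1_max: float = ENV_MAX
    e2_min: float = ENV_MIN
    e2_max: float = ENV_MAX
    step: float = Field(default=1.0, gt=0)


class _AnalysisModel(_Strict):
    min_prominence: float = Field(default=DEFAULT_MIN_PROMINENCE, ge=0)
    query_cells: list[tuple[float, float]] = Field(default_factory=list)


class _OutputModel(_Strict):
    directory: str = "."
    formats: list[str] = Field(default_factory=lambda: ["csv", "json"])
    render: bool = False


class _RunConfigModel(_Strict):
    pathway: _PathwayModel
    grid: _GridModel = Field(default_factory=_GridModel)
    analysis: _AnalysisModel = Field(default_factory=_AnalysisModel)
    output: _OutputModel = Field(default_factory=_OutputModel)
    log_level: str = "INFO"


@dataclass(frozen=True)
class RunConfig:
    """A fully validated run: pathway + grid + analysis + output options."""

    pathway: PathwayConfig
    grid: EnvGrid
    min_prominence: float
    query_cells: tuple[tuple[float, float], ...]
    output_dir: str
    formats: tuple[str, ...]
    render: bool
    log_level: str


def _response_from_model(m: _ResponseModel) -> EnvResponse:
    return EnvResponse(m.optimum, m.rate_below, m.rate_above)


def _pathway_from_model(m: _PathwayModel) -> PathwayConfig:
    return PathwayConfig(
        upstream=tuple(
            GeneCopyParams(_response_from_model(c.response_e1),
                           _response_from_model(c.response_e2), c.label)
            for c in m.upstream
        ),
        downstream=tuple(
            GeneCopyParams(_response_from_model(c.response_e1),
                           _response_from_model(c.response_e2), c.label)
            for c in m.downstream
        ),
        link_up_down=SigmoidLink(m.link_up_down.intercept, m.link_up_down.slope),
        link_down_outcome=SigmoidLink(m.link_down_outcome.intercept,
                                      m.link_down_outcome.slope),
        wiring=m.wiring,
    )


_VALUE_ERROR_TYPES = ("greater_than", "greater_than_equal", "less_than",
                      "less_than_equal", "value_error", "too_short")


def read_run_config(path) -> RunConfig:
    """Parse and validate a YAML or JSON run-configuration file.

    Raises :class:`ConfigError` with ``kind`` = ``"parse"``, ``"schema"``
    (unknown keys are rejected and named) or ``"value"``.
    """
    text = Path(path).read_text()
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"could not parse {path}: {exc}", kind="parse") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping", kind="schema")
    try:
        model = _RunConfigModel.model_validate(raw)
    except ValidationError as exc:
        details = "; ".join(
            f"{'.'.join(str(p) for p in e['loc'])}: {e['msg']}" for e in exc.errors()
        )
        kind = (
            "value"
            if all(e["type"] in _VALUE_ERROR_TYPES for e in exc.errors())
            else "schema"
        )
        raise ConfigError(f"invalid run config {path}: {details}", kind=kind) from exc
    g = model.grid
    if g.e1_min >= g.e1_max or g.e2_min >= g.e2_max:
        raise ConfigError(f"invalid run config {path}: grid min must be < max",
                          kind="value")
    try:
        pathway = _pathway_from_model(model.pathway)
    except ParameterError as exc:
        raise ConfigError(f"invalid run config {path}: {exc}", kind="value") from exc
    grid = EnvGrid(
        np.arange(g.e1_min, g.e1_max + g.step / 2, g.step, dtype=float),
        np.arange(g.e2_min, g.e2_max + g.step / 2, g.step, dtype=float),
    )
    return RunConfig(
        pathway=pathway,
        grid=grid,
        min_prominence=model.analysis.min_prominence,
        query_cells=tuple((float(a), float(b)) for a, b in model.analysis.query_cells),
        output_dir=model.output.directory,
        formats=tuple(model.output.formats),
        render=model.output.render,
        log_level=model.log_level,
    )


def config_to_dict(cfg: PathwayConfig) -> dict:
    """Plain-data representation of a pathway config (YAML/JSON friendly)."""

    def resp(r: EnvResponse):
        return {"optimum": r.optimum, "rate_below": r.rate_below,
                "rate_above": r.rate_above}

    def copy(g: GeneCopyParams):
        return {"response_e1": resp(g.response_e1),
                "response_e2": resp(g.response_e2), "label": g.label}

    wiring = cfg.wiring
    if not isinstance(wiring, str):
        wiring = {k: sorted(v) for k, v in wiring.items()}
    return {
        "upstream": [copy(g) for g in cfg.upstream],
        "downstream": [copy(g) for g in cfg.downstream],
        "link_up_down": {"intercept": cfg.link_up_down.intercept,
                         "slope": cfg.link_up_down.slope},
        "link_down_outcome": {"intercept": cfg.link_down_outcome.intercept,
                              "slope": cfg.link_down_outcome.slope},
        "wiring": wiring,
    }


def config_from_dict(data: Mapping) -> PathwayConfig:
    """Inverse of :func:`config_to_dict` (also accepts JSON string keys)."""
    model = _PathwayModel.model_validate(
        {**data, "wiring": _coerce_wiring_keys(data.get("wiring", "pooled"))}
    )
    return _pathway_from_model(model)


def _coerce_wiring_keys(wiring):
    if isinstance(wiring, Mapping):
        return {int(k): list(v) for k, v in wiring.items()}
    return wiring


def registry_to_yaml() -> str:
    """The whole figure registry as one copy-editable YAML document."""
    doc = {
        fid: {
            "notes": fc.notes,
            "pathway": config_to_dict(fc.config),
            "expected_qualitative": {
                k: (list(map(list, v)) if k == "peak_cells" else list(v))
                if isinstance(v, tuple) else v
                for k, v in fc.expected_qualitative.items()
            },
        }
        for fid, fc in sorted(_REGISTRY.items())
    }
    return yaml.safe_dump(doc, sort_keys=True)


def _atomic_write_text(path: Path, text: str):
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def surface_to_frame(surface: OutcomeSurface) -> pd.DataFrame:
    """Long-format table: e1, e2, P, U_1..U_n, D_1..D_m, one row per cell.

    Rows are row-major by e1 then e2 (e1 is the slow axis); this keeps the
    per-copy side-panel surfaces in the same file as P.
    """
    E1, E2 = np.meshgrid(surface.grid.e1_values, surface.grid.e2_values, indexing="ij")
    data = {"e1": E1.ravel(), "e2": E2.ravel(), "P": surface.P.ravel()}
    for i in range(surface.U.shape[0]):
        data[f"U_{i + 1}"] = surface.U[i].ravel()
    for j in range(surface.D.shape[0]):
        data[f"D_{j + 1}"] = surface.D[j].ravel()
    return pd.DataFrame(data)


def read_surface_csv(path, config: PathwayConfig | None = None) -> OutcomeSurface:
    """Rebuild an :class:`OutcomeSurface` from a long-format surface CSV.

    ``str(float)`` round-trips exactly, so P/U/D are restored bit-identically.
    ``config`` reattaches provenance when available; otherwise a minimal
    placeholder pathway (flat copies, links recoverable only from provenance)
    cannot be inferred and ``config`` is required for floor-based analyses.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    e1 = np.unique(df["e1"].to_numpy())
    e2 = np.unique(df["e2"].to_numpy())
    shape = (e1.size, e2.size)
    if len(df) != shape[0] * shape[1]:
        raise ConfigError(f"{path}: not a full grid", kind="schema")
    grid = EnvGrid(e1, e2)
    ucols = sorted((c for c in df.columns if c.startswith("U_")),
                   key=lambda c: int(c[2:]))
    dcols = sorted((c for c in df.columns if c.startswith("D_")),
                   key=lambda c: int(c[2:]))
    order = np.lexsort((df["e2"].to_numpy(), df["e1"].to_numpy()))
    df = df.iloc[order]
    P = df["P"].to_numpy().reshape(shape)
    U = np.stack([df[c].to_numpy().reshape(shape) for c in ucols])
    D = np.stack([df[c].to_numpy().reshape(shape) for c in dcols])
    if config is None:
        config = PathwayConfig(
            upstream=tuple(GeneCopyParams(EnvResponse(0), EnvResponse(0))
                           for _ in ucols),
            downstream=tuple(GeneCopyParams(EnvResponse(0), EnvResponse(0))
                             for _ in dcols),
            link_up_down=SigmoidLink(0, 0),
            link_down_outcome=SigmoidLink(0, 0),
        )
    return OutcomeSurface(grid=grid, P=P, U=U, D=D, config=config)


def metrics_to_jsonable(metrics: SurfaceMetrics) -> dict:
    d = dataclasses.asdict(metrics)
    d["value_at"] = {f"{k[0]},{k[1]}": v for k, v in metrics.value_at.items()}
    d["peak_optimum_distances"] = list(metrics.peak_optimum_distances)
    d["axis_halfwidths"] = list(metrics.axis_halfwidths)
    d["peak_cells"] = [list(c) for c in metrics.peak_cells]
    d["argmax"] = list(metrics.argmax)
    return d


def write_surface(
    surface: OutcomeSurface,
    directory,
    formats: Sequence[str] = ("csv", "json"),
    metrics: SurfaceMetrics | None = None,
    peaks: PeakSet | None = None,
    stem: str = "surface",
    min_prominence: float = DEFAULT_MIN_PROMINENCE,
    render: bool = False,
) -> dict[str, str]:
    """Serialize a surface (and its metrics/peaks) into ``directory``.

    Writes atomically (temp file then rename); identical inputs produce
    identical files.  Returns ``{artifact name: path}``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if metrics is None:
        metrics = breadth_metrics(surface, min_prominence)
    if peaks is None:
        peaks = find_local_maxima(surface, min_prominence)
    paths: dict[str, str] = {}
    if "csv" in formats:
        p = directory / f"{stem}.csv"
        _atomic_write_text(p, surface_to_frame(surface).to_csv(index=False))
        paths["surface_csv"] = str(p)
        pk = directory / f"{stem}_peaks.csv"
        pk_df = pd.DataFrame(list(peaks.peaks), columns=["e1", "e2", "P"])
        _atomic_write_text(pk, pk_df.to_csv(index=False))
        paths["peaks_csv"] = str(pk)
    if "json" in formats:
        p = directory / f"{stem}_metrics.json"
        _atomic_write_text(p, json.dumps(metrics_to_jsonable(metrics), indent=2,
                                         sort_keys=True) + "\n")
        paths["metrics_json"] = str(p)
    for fmt in ("png", "svg"):
        if fmt in formats or (render and fmt == "png" and "png" not in paths):
            p = directory / f"{stem}.{fmt}"
            render_heatmap(surface, p)
            paths[f"heatmap_{fmt}"] = str(p)
    return paths


def render_heatmap(surface: OutcomeSurface, path):
    """Heat map of P over the environment grid, with copy-optima markers.

    Factor 1 on the x axis, factor 2 on the y axis (both in environment
    units); white stars mark upstream optima, black stars downstream optima
    (insensitive copies are unmarked).
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    g = surface.grid
    fig, ax = plt.subplots(figsize=(5.2, 4.4))
    mesh = ax.pcolormesh(g.e1_values, g.e2_values, surface.P.T, shading="nearest",
                         vmin=0, vmax=1, cmap="viridis")
    fig.colorbar(mesh, ax=ax, label="outcome probability P")
    for copies, color in ((surface.config.upstream, "white"),
                          (surface.config.downstream, "black")):
        for g_copy in copies:
            if not (g_copy.response_e1.insensitive and g_copy.response_e2.insensitive):
                ax.plot(*g_copy.optima, marker="*", color=color, markersize=12,
                        markeredgecolor="0.4")
    ax.set_xlabel("environmental factor 1")
    ax.set_ylabel("environmental factor 2")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
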