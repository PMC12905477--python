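"""Large-vessel network data model, wall mechanics, and fixtures.

A vascular network is a rooted binary tree of compliant vessels.  Every
junction is a bifurcation (exactly two daughters); every terminal vessel
carries a self-similar structured tree of small vessels that supplies its
outflow impedance.  The wall follows a linear stress-strain law whose
stiffness Eh/r0 tapers exponentially with the unstressed radius.

Units are CGS throughout (cm, mL/s, barye); see :mod:`hemovasc.units`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

__all__ = [
    "StructuredTreeSpec",
    "VesselGeometry",
    "VascularNetwork",
    "BiophysicalParams",
    "ParameterSpace",
    "NetworkSchemaError",
    "stiffness_law",
    "pressure_from_area",
    "area_from_pressure",
    "load_network",
    "save_network",
    "fixture_network",
    "physiological_parameter_space",
]

SCHEMA_TAG = "hemonet/1"


class NetworkSchemaError(ValueError):
    """Raised when a network file or object violates the connectivity schema."""


@dataclass(frozen=True)
class StructuredTreeSpec:
    """Self-similar small-vessel tree attached to a terminal vessel.

    Daughter radii scale as r_d1 = alpha*r_p and r_d2 = beta*r_p with
    beta < alpha < 1; each vessel has length lrr*r0; the tree stops
    bifurcating below ``rmin``.
    """

    alpha: float = 0.90
    beta: float = 0.60
    lrr: float = 50.0
    rmin: float = 1e-4

    def __post_init__(self):
        if not (0.0 < self.beta < self.alpha < 1.0):
            raise ValueError(
                f"structured tree requires 0 < beta < alpha < 1, got "
                f"alpha={self.alpha}, beta={self.beta}"
            )
        if self.rmin <= 0 or self.lrr <= 0:
            raise ValueError("rmin and lrr must be positive")


@dataclass(frozen=True)
class VesselGeometry:
    id: int
    length_L: float  # cm
    radius_r0: float  # cm, unstressed
    parent: int | None = None
    daughters: tuple[int, ...] = ()
    group: int = 0
    terminal_tree: StructuredTreeSpec | None = None

    def __post_init__(self):
        if self.length_L <= 0:
            raise ValueError(f"vessel {self.id}: length must be positive")
        if self.radius_r0 <= 0:
            raise ValueError(f"vessel {self.id}: radius must be positive")
        if len(self.daughters) not in (0, 2):
            raise NetworkSchemaError(
                f"vessel {self.id}: every junction must have exactly two "
                f"daughters (got {len(self.daughters)})"
            )

    @property
    def is_terminal(self) -> bool:
        return len(self.daughters) == 0

    @property
    def A0(self) -> float:
        return math.pi * self.radius_r0**2


class VascularNetwork:
    """Validated rooted binary tree of :class:`VesselGeometry`."""

    def __init__(self, vessels: list[VesselGeometry]):
        self.vessels = {v.id: v for v in vessels}
        if len(self.vessels) != len(vessels):
            raise NetworkSchemaError("duplicate vessel ids")
        self._validate()

    def _validate(self):
        roots = [v for v in self.vessels.values() if v.parent is None]
        if len(roots) != 1:
            raise NetworkSchemaError(
                f"network must have exactly one root vessel, found "
                f"{[v.id for v in roots]}"
            )
        self.root = roots[0]
        # daughters exist, parent links consistent, acyclic (tree reachability)
        seen = set()
        stack = [self.root.id]
        while stack:
            vid = stack.pop()
            if vid in seen:
                raise NetworkSchemaError(f"cyclic connectivity at vessel {vid}")
            seen.add(vid)
            v = self.vessels[vid]
            for d in v.daughters:
                if d not in self.vessels:
                    raise NetworkSchemaError(
                        f"vessel {vid} lists unknown daughter {d}"
                    )
                if self.vessels[d].parent != vid:
                    raise NetworkSchemaError(
                        f"vessel {d} parent link does not match junction of "
                        f"vessel {vid}"
                    )
                stack.append(d)
        if seen != set(self.vessels):
            orphans = sorted(set(self.vessels) - seen)
            raise NetworkSchemaError(f"vessels unreachable from root: {orphans}")
        for v in self.vessels.values():
            if v.is_terminal and v.terminal_tree is None:
                raise NetworkSchemaError(
                    f"terminal vessel {v.id} is missing its structured tree"
                )
            if not v.is_terminal and v.terminal_tree is not None:
                raise NetworkSchemaError(
                    f"interior vessel {v.id} must not carry a structured tree"
                )

    # -- convenience views -------------------------------------------------
    @property
    def n_vessels(self) -> int:
        return len(self.vessels)

    @property
    def junctions(self) -> list[tuple[int, int, int]]:
        """(parent, daughter1, daughter2) triples."""
        return [
            (v.id, *v.daughters)
            for v in self.vessels.values()
            if not v.is_terminal
        ]

    @property
    def terminal_ids(self) -> list[int]:
        return sorted(v.id for v in self.vessels.values() if v.is_terminal)

    @property
    def n_groups(self) -> int:
        return 1 + max(v.group for v in self.vessels.values())

    def ordered_ids(self) -> list[int]:
        """Vessel ids in breadth-first order from the root."""
        out, queue = [], [self.root.id]
        while queue:
            vid = queue.pop(0)
            out.append(vid)
            queue.extend(self.vessels[vid].daughters)
        return out

    def __eq__(self, other):
        return isinstance(other, VascularNetwork) and self.vessels == other.vessels


# ---------------------------------------------------------------------------
# Wall mechanics
# ---------------------------------------------------------------------------

def stiffness_law(r0, f1, f2, f3):
    """Wall stiffness Eh/r0 = f1*exp(-f2*r0) + f3 (g cm^-1 s^-2).

    Strictly decreasing in r0 for f1, f2 > 0: small vessels are stiffer.
    """
    r0 = np.asarray(r0, dtype=float)
    if np.any(r0 <= 0):
        raise ValueError("unstressed radius must be positive")
    out = f1 * np.exp(-f2 * r0) + f3
    return out if out.ndim else float(out)


def pressure_from_area(A, r0, Eh_over_r0, p0=0.0):
    """Linear stress-strain law: p - p0 = (4/3)(Eh/r0)(sqrt(A/A0) - 1)."""
    A = np.asarray(A, dtype=float)
    if np.any(A <= 0):
        raise ValueError("cross-sectional area must be positive")
    A0 = math.pi * r0**2
    out = p0 + (4.0 / 3.0) * Eh_over_r0 * (np.sqrt(A / A0) - 1.0)
    return out if out.ndim else float(out)


def area_from_pressure(p, r0, Eh_over_r0, p0=0.0):
    """Invert the wall law: A = A0*[(3/(4 Eh/r0))(p - p0) + 1]^2."""
    p = np.asarray(p, dtype=float)
    A0 = math.pi * r0**2
    bracket = 3.0 / (4.0 * Eh_over_r0) * (p - p0) + 1.0
    if np.any(bracket <= 0):
        raise ValueError(
            "pressure outside the wall model's validity (collapse regime)"
        )
    out = A0 * bracket**2
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Biophysical parameters
# ---------------------------------------------------------------------------

@dataclass
class BiophysicalParams:
    """Wall-stiffness and fluid constants; the inferable subset lives in a
    :class:`ParameterSpace` vector.

    f3 entries are per stiffness group (one group for the 9-vessel model,
    four for the 17-vessel model).
    """

    f2_large: float = 35.0  # 1/cm
    f2_small: float = 35.0
    f3_large_by_group: tuple[float, ...] = (5.5e5,)  # g/cm/s^2
    f3_small_by_group: tuple[float, ...] = (5.5e5,)
    alpha: float = 0.90
    f1_large: float = 2.0e8
    f1_small: float = 2.0e8
    rho: float = 1.057  # g/cm^3
    mu: float = 0.032  # g/cm/s
    p0: float = 0.0  # barye, gauge
    period_T: float = 1.0  # s

    @property
    def nu(self) -> float:
        """Kinematic viscosity (cm^2/s)."""
        return self.mu / self.rho

    def large_vessel_stiffness(self, r0: float, group: int = 0) -> float:
        return stiffness_law(
            r0, self.f1_large, self.f2_large, self.f3_large_by_group[group]
        )

    def small_vessel_stiffness(self, r0, group: int = 0):
        return stiffness_law(
            r0, self.f1_small, self.f2_small, self.f3_small_by_group[group]
        )


@dataclass
class ParameterSpace:
    """Ordered inferable components theta with box bounds.

    ``names`` use the pattern ``f2_large``, ``f2_small``, ``f3_large[g]``,
    ``f3_small[g]``, ``alpha``.
    """

    names: tuple[str, ...]
    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self):
        self.lower = np.asarray(self.lower, float)
        self.upper = np.asarray(self.upper, float)
        if not (
            len(self.names) == self.lower.size == self.upper.size
        ):
            raise ValueError("names/bounds size mismatch")
        if np.any(self.lower >= self.upper):
            raise ValueError("need lo < hi componentwise")

    @property
    def dim(self) -> int:
        return len(self.names)

    def contains(self, theta) -> bool:
        theta = np.asarray(theta, float)
        return bool(
            np.all(theta >= self.lower - 1e-12)
            and np.all(theta <= self.upper + 1e-12)
        )

    def normalise(self, theta):
        """Min-max scale theta into [0, 1]^dim."""
        return (np.asarray(theta, float) - self.lower) / (self.upper - self.lower)

    def denormalise(self, z):
        return self.lower + np.asarray(z, float) * (self.upper - self.lower)

    def to_vector(self, params: BiophysicalParams) -> np.ndarray:
        return np.array([_get_component(params, n) for n in self.names])

    def update_params(self, base: BiophysicalParams, theta) -> BiophysicalParams:
        theta = np.asarray(theta, float)
        out = replace(base)
        f3l = list(out.f3_large_by_group)
        f3s = list(out.f3_small_by_group)
        for name, val in zip(self.names, theta):
            if name == "f2_large":
                out.f2_large = float(val)
            elif name == "f2_small":
                out.f2_small = float(val)
            elif name == "alpha":
                out.alpha = float(val)
            elif name.startswith("f3_large["):
                f3l[int(name[9:-1])] = float(val)
            elif name.startswith("f3_small["):
                f3s[int(name[9:-1])] = float(val)
            else:
                raise KeyError(f"unknown parameter component {name!r}")
        out.f3_large_by_group = tuple(f3l)
        out.f3_small_by_group = tuple(f3s)
        return out


def _get_component(params: BiophysicalParams, name: str) -> float:
    if name == "f2_large":
        return params.f2_large
    if name == "f2_small":
        return params.f2_small
    if name == "alpha":
        return params.alpha
    if name.startswith("f3_large["):
        return params.f3_large_by_group[int(name[9:-1])]
    if name.startswith("f3_small["):
        return params.f3_small_by_group[int(name[9:-1])]
    raise KeyError(f"unknown parameter component {name!r}")


def physiological_parameter_space(n_groups: int = 1, include=None) -> ParameterSpace:
    """Inferable-parameter box for the single-group (5-parameter) or
    four-group (10-parameter) models: f2 in [25,45], f3 in [2e5,9e5]
    (per group, large and small), alpha in [0.85,0.94].
    """
    names, lo, hi = [], [], []

    def add(name, a, b):
        if include is None or name in include:
            names.append(name)
            lo.append(a)
            hi.append(b)

    add("f2_large", 25.0, 45.0)
    add("f2_small", 25.0, 45.0)
    for g in range(n_groups):
        add(f"f3_large[{g}]", 2.0e5, 9.0e5)
    for g in range(n_groups):
        add(f"f3_small[{g}]", 2.0e5, 9.0e5)
    add("alpha", 0.85, 0.94)
    return ParameterSpace(tuple(names), np.array(lo), np.array(hi))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def save_network(network: VascularNetwork, path) -> None:
    doc = {
        "format": SCHEMA_TAG,
        "vessels": [
            {
                "id": v.id,
                "length_cm": float(v.length_L),
                "radius_cm": float(v.radius_r0),
                "daughters": list(v.daughters),
                "group": v.group,
            }
            for v in network.vessels.values()
        ],
        "trees": [
            {
                "vessel_id": v.id,
                "alpha": v.terminal_tree.alpha,
                "beta": v.terminal_tree.beta,
                "lrr": v.terminal_tree.lrr,
                "rmin": v.terminal_tree.rmin,
            }
            for v in network.vessels.values()
            if v.terminal_tree is not None
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_network(path) -> VascularNetwork:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or doc.get("format") != SCHEMA_TAG:
        raise NetworkSchemaError(
            f"not a {SCHEMA_TAG} network file: {path}"
        )
    trees = {
        t["vessel_id"]: StructuredTreeSpec(
            alpha=t["alpha"], beta=t["beta"], lrr=t["lrr"], rmin=t["rmin"]
        )
        for t in doc.get("trees", [])
    }
    # reconstruct parent links from daughter lists
    parent_of = {}
    for rec in doc["vessels"]:
        for d in rec["daughters"]:
            parent_of[d] = rec["id"]
    vessels = []
    for rec in doc["vessels"]:
        vid = rec["id"]
        vessels.append(
            VesselGeometry(
                id=vid,
                length_L=rec["length_cm"],
                radius_r0=rec["radius_cm"],
                parent=parent_of.get(vid),
                daughters=tuple(rec["daughters"]),
                group=rec.get("group", 0),
                terminal_tree=trees.get(vid),
            )
        )
    return VascularNetwork(vessels)


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

def _tree(rmin=1e-4, alpha=0.90):
    return StructuredTreeSpec(alpha=alpha, beta=0.60, lrr=50.0, rmin=rmin)


def fixture_network(kind: str, seed: int | None = None) -> VascularNetwork:
    """Synthetic, dimensionally plausible test networks.

    Topologies mirror the aorta/head-and-neck layout (the nine-vessel kind
    reproduces the aorta chain with neck branches; seventeen extends it into
    the arms and head with four stiffness groups).  Lengths and radii are
    synthetic stand-ins for patient geometry; a nonzero ``seed`` jitters
    them by a few percent for perturbed-geometry studies.
    """
    if kind == "single_vessel":
        vessels = [
            VesselGeometry(1, length_L=8.0, radius_r0=0.6, terminal_tree=_tree())
        ]
    elif kind == "bifurcation3":
        vessels = [
            VesselGeometry(1, 6.0, 0.60, daughters=(2, 3)),
            VesselGeometry(2, 5.0, 0.48, parent=1, terminal_tree=_tree()),
            VesselGeometry(3, 4.0, 0.38, parent=1, terminal_tree=_tree()),
        ]
    elif kind == "nine_vessel":
        # 1 ascending aorta -> (3 innominate, 2 arch I); 2 -> (5 l. carotid,
        # 4 arch II); 4 -> (6 l. subclavian, 7 descending aorta);
        # 3 -> (8 r. subclavian, 9 r. carotid).  Vessel 7 uses rmin=1e-3.
        vessels = [
            VesselGeometry(1, 4.0, 0.80, daughters=(3, 2)),
            VesselGeometry(2, 2.5, 0.70, parent=1, daughters=(5, 4)),
            VesselGeometry(3, 3.0, 0.45, parent=1, daughters=(8, 9)),
            VesselGeometry(4, 2.5, 0.65, parent=2, daughters=(6, 7)),
            VesselGeometry(5, 8.0, 0.28, parent=2, terminal_tree=_tree()),
            VesselGeometry(6, 8.0, 0.32, parent=4, terminal_tree=_tree()),
            VesselGeometry(7, 14.0, 0.55, parent=4, terminal_tree=_tree(rmin=1e-3)),
            VesselGeometry(8, 8.0, 0.32, parent=3, terminal_tree=_tree()),
            VesselGeometry(9, 8.0, 0.26, parent=3, terminal_tree=_tree()),
        ]
    elif kind == "seventeen_vessel":
        # extend nine_vessel: carotids split into internal/external, the
        # subclavians continue into brachial/vertebral.  Four stiffness
        # groups: 0 aortic trunk, 1 neck, 2 arms, 3 head.
        vessels = [
            VesselGeometry(1, 4.0, 0.80, daughters=(3, 2), group=0),
            VesselGeometry(2, 2.5, 0.70, parent=1, daughters=(5, 4), group=0),
            VesselGeometry(3, 3.0, 0.45, parent=1, daughters=(8, 9), group=1),
            VesselGeometry(4, 2.5, 0.65, parent=2, daughters=(6, 7), group=0),
            VesselGeometry(5, 8.0, 0.28, parent=2, daughters=(10, 11), group=1),
            VesselGeometry(6, 8.0, 0.32, parent=4, daughters=(12, 13), group=2),
            VesselGeometry(7, 14.0, 0.55, parent=4, terminal_tree=_tree(rmin=1e-3), group=0),
            VesselGeometry(8, 8.0, 0.32, parent=3, daughters=(14, 15), group=2),
            VesselGeometry(9, 8.0, 0.26, parent=3, daughters=(16, 17), group=1),
            VesselGeometry(10, 6.0, 0.20, parent=5, terminal_tree=_tree(), group=3),
            VesselGeometry(11, 6.0, 0.16, parent=5, terminal_tree=_tree(), group=3),
            VesselGeometry(12, 10.0, 0.24, parent=6, terminal_tree=_tree(), group=2),
            VesselGeometry(13, 7.0, 0.14, parent=6, terminal_tree=_tree(), group=3),
            VesselGeometry(14, 10.0, 0.24, parent=8, terminal_tree=_tree(), group=2),
            VesselGeometry(15, 7.0, 0.14, parent=8, terminal_tree=_tree(), group=3),
            VesselGeometry(16, 6.0, 0.19, parent=9, terminal_tree=_tree(), group=3),
            VesselGeometry(17, 6.0, 0.15, parent=9, terminal_tree=_tree(), group=3),
        ]
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")

    if seed:
        rng = np.random.default_rng(seed)
        jittered = []
        for v in vessels:
            jittered.append(
                replace(
                    v,
                    length_L=v.length_L * (1 + 0.03 * rng.standard_normal()),
                    radius_r0=v.radius_r0 * (1 + 0.03 * rng.standard_normal()),
                )
            )
        vessels = jittered
    return VascularNetwork(vessels)
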