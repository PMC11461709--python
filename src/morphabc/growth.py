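"""Stochastic agent-based simulation of neurite outgrowth.

Two resource-driven growth rules are implemented on a tree of cylindrical
agents attached to a spherical soma:

* **Model 1** (symmetric bifurcation): an elongating tip splits into two
  daughter tips with probability ``p_bra`` per time step; both daughters
  inherit the mother's remaining resource.  Typical of basal dendrites.
* **Model 2** (asymmetric side-branching): the tip continues in a straight
  line and sheds a side branch with probability ``p_bra``; the continuation
  inherits the resource while the side branch starts from a fixed budget
  ``r_0``.  Additionally *every* agent's resource decays by ``R`` per step
  until it reaches (or slightly undershoots) ``r_min``.  Typical of apical
  dendrites with a dominant main branch.

Elongation is a persistent, biased random walk: the new direction is the
normalised weighted sum of a uniformly random unit vector, the tip's current
orientation and the (normalised) gradient of an external guidance cue.
Elongation consumes ``R`` resource units; a tip whose resource falls to
``r_min`` or below becomes idle and never reactivates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

__all__ = [
    "ModelParams",
    "AgentNode",
    "NeuronTree",
    "GuidanceField",
    "LinearField",
    "DegenerateDirectionError",
    "elongation_direction",
    "apply_elongation",
    "branch_tip",
    "step_model",
    "simulate_neuron",
    "simulate_dataset",
    "initial_tree",
]

SOMA = "soma"
NEURITE = "neurite"

# SWC structure identifiers used for the ``subtype`` of neurite agents.
BASAL = 3
APICAL = 4


class DegenerateDirectionError(ValueError):
    """Raised when the elongation direction has (numerically) zero length."""


@dataclass
class ModelParams:
    """Growth-rule parameters.  All rates are per time step (``dt = 1``).

    The defaults are the Model-2 conditions of the synthetic calibration
    study: branching probability ``p_bra = 0.38e-1`` per tip per step,
    resource consumption ``R = 0.71e-3`` per elongation/decay event and
    elongation speed ``v = 1e2`` length units per step.
    """

    model_id: int = 2
    p_bra: float = 0.038
    R: float = 0.71e-3
    v: float = 100.0
    r_min: float = 0.0
    r_init: float = 1.0
    r_0: float = 0.01
    dt: float = 1.0
    n_steps: int = 500
    w_rand: float = 0.4
    w_old: float = 0.5
    w_grad: float = 0.1
    l_max: float = 10.0
    theta_bifurcate_deg: float = 30.0
    theta_side_deg: float = 60.0
    #: hard cap on the number of agents; a guard against parameter corners
    #: where the branching process is supercritical.
    max_agents: int = 200_000

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_bra <= 1.0:
            raise ValueError(f"p_bra must be in [0, 1], got {self.p_bra}")
        if self.v < 0 or self.R < 0:
            raise ValueError("v and R must be non-negative")
        if self.r_init <= self.r_min:
            raise ValueError("r_init must exceed r_min")
        if self.l_max <= 0:
            raise ValueError("l_max must be positive")
        w = (self.w_rand, self.w_old, self.w_grad)
        if any(x < 0 for x in w) or all(x == 0 for x in w):
            raise ValueError("direction weights must be >= 0 and not all zero")
        if self.model_id not in (1, 2):
            raise ValueError(f"model_id must be 1 or 2, got {self.model_id}")

    @property
    def weights(self) -> tuple[float, float, float]:
        return (self.w_rand, self.w_old, self.w_grad)


@dataclass
class AgentNode:
    """A cylindrical agent (or the spherical soma) in the neuron tree."""

    id: int
    kind: str  # SOMA | NEURITE
    start: np.ndarray
    end: np.ndarray
    diameter: float = 1.0
    resource: float = 0.0
    parent: int | None = None
    children: list[int] = field(default_factory=list)
    subtype: int = BASAL  # SWC structure code (3 basal, 4 apical)
    # unit orientation of the cylinder; kept explicitly so that zero-length
    # daughters created at a branch point have a well-defined heading
    orientation: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 0.0, 1.0])
    )

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.end - self.start))

    def is_tip(self) -> bool:
        return self.kind == NEURITE and not self.children


class NeuronTree:
    """Rooted tree of agents: one soma plus neurite cylinders."""

    def __init__(self, soma_position=(0.0, 0.0, 0.0), soma_radius: float = 7.5):
        self.soma_position = np.asarray(soma_position, dtype=float)
        self.soma_radius = float(soma_radius)
        self.nodes: dict[int, AgentNode] = {}
        self._next_id = 1
        soma = AgentNode(
            id=self._take_id(),
            kind=SOMA,
            start=self.soma_position.copy(),
            end=self.soma_position.copy(),
            diameter=2.0 * soma_radius,
        )
        self.nodes[soma.id] = soma
        self.soma_id = soma.id

    def _take_id(self) -> int:
        i = self._next_id
        self._next_id += 1
        return i

    def add_node(self, **kwargs) -> AgentNode:
        node = AgentNode(id=self._take_id(), **kwargs)
        self.nodes[node.id] = node
        if node.parent is not None:
            self.nodes[node.parent].children.append(node.id)
        return node

    # -- queries ---------------------------------------------------------
    def neurites(self) -> Iterable[AgentNode]:
        return (n for n in self.nodes.values() if n.kind == NEURITE)

    def tips(self) -> list[AgentNode]:
        return sorted((n for n in self.neurites() if n.is_tip()), key=lambda n: n.id)

    def total_length(self) -> float:
        return sum(n.length for n in self.neurites())

    def n_agents(self) -> int:
        return len(self.nodes)

    def validate(self) -> None:
        """Check structural invariants; raise ``ValueError`` on violation."""
        ids = set(self.nodes)
        roots = 0
        for n in self.nodes.values():
            if n.parent is None:
                roots += 1
                if n.kind != SOMA:
                    raise ValueError(f"non-soma root agent {n.id}")
            else:
                if n.parent not in ids:
                    raise ValueError(f"agent {n.id} has dangling parent {n.parent}")
                parent = self.nodes[n.parent]
                if n.id not in parent.children:
                    raise ValueError(f"parent/child link inconsistent at {n.id}")
                if parent.kind == NEURITE and not np.allclose(
                    parent.end, n.start, atol=1e-9
                ):
                    raise ValueError(
                        f"agent {n.id} start does not coincide with parent end"
                    )
            if n.kind == NEURITE and len(n.children) > 2:
                raise ValueError(f"agent {n.id} has {len(n.children)} children")
        if roots != 1:
            raise ValueError(f"tree must have exactly one root, found {roots}")
        # acyclicity: every node must reach the soma
        for n in self.nodes.values():
            seen = set()
            cur = n
            while cur.parent is not None:
                if cur.id in seen:
                    raise ValueError("cycle detected")
                seen.add(cur.id)
                cur = self.nodes[cur.parent]

    def copy(self) -> "NeuronTree":
        new = NeuronTree.__new__(NeuronTree)
        new.soma_position = self.soma_position.copy()
        new.soma_radius = self.soma_radius
        new.soma_id = self.soma_id
        new._next_id = self._next_id
        new.nodes = {
            i: replace(
                n,
                start=n.start.copy(),
                end=n.end.copy(),
                children=list(n.children),
                orientation=n.orientation.copy(),
            )
            for i, n in self.nodes.items()
        }
        return new


class GuidanceField:
    """Scalar guidance cue phi(x, t) with gradient; base class."""

    def value(self, x: np.ndarray, t: float = 0.0) -> float:
        raise NotImplementedError

    def gradient(self, x: np.ndarray, t: float = 0.0) -> np.ndarray:
        raise NotImplementedError


class LinearField(GuidanceField):
    """phi(x) = g . x — a constant-gradient cue (default: apical, +z)."""

    def __init__(self, direction=(0.0, 0.0, 1.0)):
        self.g = np.asarray(direction, dtype=float)

    def value(self, x, t=0.0):
        return float(np.dot(self.g, x))

    def gradient(self, x, t=0.0):
        return self.g.copy()


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise DegenerateDirectionError("zero-length direction vector")
    return v / n


def _random_unit_vector(rng: np.random.Generator) -> np.ndarray:
    while True:
        u = rng.standard_normal(3)
        n = np.linalg.norm(u)
        if n > 1e-12:
            return u / n


def elongation_direction(
    orientation: np.ndarray,
    gradient: np.ndarray,
    weights: tuple[float, float, float],
    rng: np.random.Generator,
) -> np.ndarray:
    """Direction of the persistent, biased random walk.

    Returns ``d / ||d||`` where ``d = w_rand*u + w_old*orientation +
    w_grad*g_hat`` with ``u`` a uniformly random unit vector and ``g_hat``
    the normalised guidance gradient (zero vector if the gradient vanishes).
    """
    w_rand, w_old, w_grad = weights
    u = _random_unit_vector(rng) if w_rand > 0 else np.zeros(3)
    gn = np.linalg.norm(gradient)
    g_hat = gradient / gn if gn > 1e-12 else np.zeros(3)
    d = w_rand * u + w_old * np.asarray(orientation, float) + w_grad * g_hat
    return _unit(d)


def _rotate_about(orientation: np.ndarray, theta: float, psi: float) -> np.ndarray:
    """Rotate ``orientation`` away by polar angle ``theta`` at azimuth ``psi``."""
    o = _unit(np.asarray(orientation, float))
    # orthonormal frame around o
    a = np.array([1.0, 0.0, 0.0]) if abs(o[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    n1 = _unit(np.cross(o, a))
    n2 = np.cross(o, n1)
    return math.cos(theta) * o + math.sin(theta) * (
        math.cos(psi) * n1 + math.sin(psi) * n2
    )


def apply_elongation(
    tree: NeuronTree,
    tip: AgentNode,
    direction: np.ndarray,
    params: ModelParams,
) -> AgentNode:
    """Shift the tip endpoint by ``v * direction`` and consume ``R`` resource.

    The tip cylinder is the straight chord from its start to its (moving)
    endpoint.  If the chord exceeds ``l_max`` it is split into two collinear
    halves; the distal half becomes the new tip and carries the resource.
    Returns the (possibly new) tip agent.
    """
    tip.end = tip.end + params.v * np.asarray(direction, float)
    tip.resource -= params.R
    chord = tip.end - tip.start
    length = np.linalg.norm(chord)
    if length > 1e-12:
        tip.orientation = chord / length
    if length > params.l_max:
        mid = tip.start + 0.5 * chord
        distal = tree.add_node(
            kind=NEURITE,
            start=mid.copy(),
            end=tip.end.copy(),
            diameter=tip.diameter,
            resource=tip.resource,
            parent=tip.id,
            subtype=tip.subtype,
            orientation=tip.orientation.copy(),
        )
        tip.end = mid
        tip.resource = 0.0  # internal agents hold no growth budget in Model 1
        return distal
    return tip


def branch_tip(
    tree: NeuronTree,
    tip: AgentNode,
    params: ModelParams,
    rng: np.random.Generator,
) -> list[AgentNode]:
    """Create daughter tips at a branching event.

    Model 1: two daughters deflected symmetrically by ``theta_bifurcate``
    within a random plane through the mother's orientation; both inherit
    the mother's resource.  Model 2: a continuation daughter keeps the
    orientation and resource; a side branch is deflected by ``theta_side``
    at a random azimuth and starts with resource ``r_0``.
    """
    if not tip.is_tip():
        raise ValueError(f"branch_tip called on non-tip agent {tip.id}")
    psi = rng.uniform(0.0, 2.0 * math.pi)
    daughters: list[AgentNode] = []
    if params.model_id == 1:
        theta = math.radians(params.theta_bifurcate_deg)
        for off in (0.0, math.pi):
            d = _rotate_about(tip.orientation, theta, psi + off)
            daughters.append(
                tree.add_node(
                    kind=NEURITE,
                    start=tip.end.copy(),
                    end=tip.end.copy(),
                    diameter=tip.diameter,
                    resource=tip.resource,
                    parent=tip.id,
                    subtype=tip.subtype,
                    orientation=d,
                )
            )
        tip.resource = 0.0
    else:
        daughters.append(
            tree.add_node(
                kind=NEURITE,
                start=tip.end.copy(),
                end=tip.end.copy(),
                diameter=tip.diameter,
                resource=tip.resource,
                parent=tip.id,
                subtype=tip.subtype,
                orientation=tip.orientation.copy(),
            )
        )
        side = _rotate_about(tip.orientation, math.radians(params.theta_side_deg), psi)
        daughters.append(
            tree.add_node(
                kind=NEURITE,
                start=tip.end.copy(),
                end=tip.end.copy(),
                diameter=tip.diameter,
                resource=params.r_0,
                parent=tip.id,
                subtype=tip.subtype,
                orientation=side,
            )
        )
        tip.resource = 0.0
    return daughters


def step_model(
    tree: NeuronTree,
    params: ModelParams,
    fld: GuidanceField,
    rng: np.random.Generator,
    t: float = 0.0,
) -> NeuronTree:
    """Advance the tree by one time step (in place; the tree is returned).

    Every tip that is active at the start of the step (``resource > r_min``)
    elongates and independently branches with probability ``p_bra``.  For
    Model 2 a global decay of ``R`` per agent is applied last, stopping once
    an agent's resource reaches or falls below ``r_min``.
    """
    if tree.n_agents() < params.max_agents:
        for tip in tree.tips():
            if tip.resource <= params.r_min:
                continue
            d = elongation_direction(
                tip.orientation, fld.gradient(tip.end, t), params.weights, rng
            )
            tip = apply_elongation(tree, tip, d, params)
            if rng.random() < params.p_bra:
                branch_tip(tree, tip, params, rng)
    if params.model_id == 2:
        for node in tree.neurites():
            if node.resource > params.r_min:
                node.resource -= params.R
    return tree


def initial_tree(
    n_basal: int = 0,
    n_apical: int = 1,
    stub_length: float = 10.0,
    soma_radius: float = 7.5,
    r_init: float = 1.0,
    diameter: float = 1.0,
) -> NeuronTree:
    """Soma at the origin with apical stubs (+z) and basal stubs (-z cone).

    Stub directions are deterministic: apical stubs point along +z, basal
    stubs are spread at fixed azimuths 45 degrees below the xy-plane.
    Stubs are anchored at the soma centre and have length ``stub_length``.
    """
    tree = NeuronTree(soma_radius=soma_radius)
    dirs: list[tuple[np.ndarray, int]] = []
    for k in range(n_apical):
        phi = 2.0 * math.pi * k / max(n_apical, 1)
        d = np.array([0.0, 0.0, 1.0])
        if n_apical > 1:  # small fan so that stubs do not coincide
            d = _unit(np.array([0.2 * math.cos(phi), 0.2 * math.sin(phi), 1.0]))
        dirs.append((d, APICAL))
    for k in range(n_basal):
        phi = 2.0 * math.pi * k / max(n_basal, 1)
        d = _unit(np.array([math.cos(phi), math.sin(phi), -1.0]))
        dirs.append((d, BASAL))
    for d, subtype in dirs:
        # roots are anchored at the soma centre (standard SWC convention:
        # the first neurite point's parent is the soma record)
        start = tree.soma_position.copy()
        tree.add_node(
            kind=NEURITE,
            start=start,
            end=start + stub_length * d,
            diameter=diameter,
            resource=r_init,
            parent=tree.soma_id,
            subtype=subtype,
            orientation=d.copy(),
        )
    return tree


def default_init(params: ModelParams) -> NeuronTree:
    """The standard initial configuration for a given model.

    Model 2 grows a single apical stub; Model 1 grows two basal stubs.
    """
    if params.model_id == 2:
        return initial_tree(n_basal=0, n_apical=1, r_init=params.r_init)
    return initial_tree(n_basal=2, n_apical=0, r_init=params.r_init)


def simulate_neuron(
    params: ModelParams,
    init: NeuronTree | None = None,
    fld: GuidanceField | None = None,
    seed: int = 0,
) -> NeuronTree:
    """Run ``n_steps`` growth steps from ``init``; deterministic given seed."""
    if init is None:
        init = default_init(params)
    if fld is None:
        fld = LinearField()
    init.validate()
    if not any(True for _ in init.neurites()):
        raise ValueError("initial tree must contain at least one neurite stub")
    tree = init.copy()
    rng = np.random.default_rng(seed)
    for k in range(params.n_steps):
        step_model(tree, params, fld, rng, t=k * params.dt)
    return tree


def simulate_dataset(
    params: ModelParams,
    init: NeuronTree | None = None,
    fld: GuidanceField | None = None,
    m: int = 1,
    seed: int = 0,
) -> list[NeuronTree]:
    """``m`` independent neurons from child seeds derived from ``seed``."""
    if m < 1:
        raise ValueError("m must be >= 1")
    child_seeds = np.random.SeedSequence(seed).generate_state(m)
    return [
        simulate_neuron(params, init, fld, seed=int(s)) for s in child_seeds
    ]
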