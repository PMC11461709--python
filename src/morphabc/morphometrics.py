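"""Morphometric quantification of neuron trees.

A neuron is reduced to the four-dimensional quantity-of-interest (QoI)
vector

* ``m1_n_segments``   — number of segments,
* ``m2_mean_seg_len`` — mean segment length,
* ``m3_std_seg_len``  — standard deviation of segment lengths (population
  convention by default),
* ``m4_total_len``    — total dendritic length.

A *segment* is a maximal unbranched section between topological nodes
(soma attachment, branch points, tips); its length is the sum of its
constituent cylinder lengths.  This convention makes the QoIs invariant to
the simulator's ``l_max`` discretisation splits.  The soma is excluded;
apical (SWC type 4) and basal (type 3) subtrees can be selected separately.
"""

from __future__ import annotations

from os import PathLike
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .growth import APICAL, BASAL, SOMA, AgentNode, NeuronTree

__all__ = [
    "QOI_COLUMNS",
    "extract_sections",
    "section_lengths",
    "compute_morphometrics",
    "dataset_qois",
]

QOI_COLUMNS = ["m1_n_segments", "m2_mean_seg_len", "m3_std_seg_len", "m4_total_len"]

_SELECTIONS = {"all": (APICAL, BASAL), "apical": (APICAL,), "basal": (BASAL,)}


def _selected_roots(tree: NeuronTree, selection: str) -> list[AgentNode]:
    try:
        subtypes = _SELECTIONS[selection]
    except KeyError:
        raise ValueError(f"selection must be one of {sorted(_SELECTIONS)}") from None
    soma = tree.nodes[tree.soma_id]
    return [
        tree.nodes[c]
        for c in sorted(soma.children)
        if tree.nodes[c].subtype in subtypes
    ]


def extract_sections(tree: NeuronTree, selection: str = "all") -> list[list[AgentNode]]:
    """Maximal unbranched agent chains between topological nodes.

    Each returned section is the list of its constituent cylinder agents in
    root-to-tip order.
    """
    sections: list[list[AgentNode]] = []
    stack = [[root] for root in reversed(_selected_roots(tree, selection))]
    while stack:
        chain = stack.pop()
        node = chain[-1]
        while len(node.children) == 1:
            node = tree.nodes[node.children[0]]
            chain.append(node)
        sections.append(chain)
        for c in sorted(node.children, reverse=True):
            stack.append([tree.nodes[c]])
    return sections


def section_lengths(tree: NeuronTree, selection: str = "all") -> np.ndarray:
    return np.array(
        [sum(a.length for a in sec) for sec in extract_sections(tree, selection)]
    )


def compute_morphometrics(
    tree: NeuronTree, selection: str = "all", ddof: int = 0
) -> pd.Series:
    """QoI vector of one neuron; ``ddof=0`` is the population-sigma default."""
    lens = section_lengths(tree, selection)
    if lens.size == 0:
        raise ValueError(f"no sections for selection {selection!r}")
    return pd.Series(
        {
            "m1_n_segments": float(lens.size),
            "m2_mean_seg_len": float(lens.mean()),
            "m3_std_seg_len": float(lens.std(ddof=ddof)),
            "m4_total_len": float(lens.sum()),
        }
    )


def qois_from_sections(lens: np.ndarray, ddof: int = 0) -> np.ndarray:
    """QoI vector from a raw array of section lengths."""
    lens = np.asarray(lens, float)
    return np.array([lens.size, lens.mean(), lens.std(ddof=ddof), lens.sum()])


def dataset_qois(
    neurons: Sequence[NeuronTree] | Sequence[str | PathLike],
    selection: str = "all",
    labels: Sequence[str] | None = None,
    ddof: int = 0,
) -> pd.DataFrame:
    """QoI matrix (one row per neuron, in input order).

    Accepts in-memory trees or paths to SWC files.  Per-neuron failures are
    re-raised with the neuron's label attached.
    """
    from .swc import read_swc

    rows = []
    idx = []
    for k, item in enumerate(neurons):
        if isinstance(item, NeuronTree):
            tree, label = item, f"neuron_{k}"
        else:
            tree, label = read_swc(item), str(item)
        if labels is not None:
            label = labels[k]
        try:
            rows.append(compute_morphometrics(tree, selection, ddof=ddof))
        except Exception as exc:
            raise type(exc)(f"{label}: {exc}") from exc
        idx.append(label)
    if not rows:
        raise ValueError("at least one neuron is required")
    return pd.DataFrame(rows, index=idx, columns=QOI_COLUMNS)
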