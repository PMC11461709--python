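"""Reading and writing neuron morphologies in the 7-column SWC format.

Records are ``id type x y z radius parent`` with ``#`` comments, 1-based
ids in parent-before-child order and root parent ``-1``.  Type codes follow
the standard convention: 1 soma, 3 basal dendrite, 4 apical dendrite.

Points are node endpoints; the cylinder between a parent point and a child
point belongs to the child record.  A neurite record whose parent is the
soma carries the cylinder from the soma point to the record point (the
convention the growth simulator follows: neurite roots are anchored at the
soma centre).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .growth import APICAL, BASAL, NEURITE, SOMA, NeuronTree

__all__ = ["SWCFormatError", "read_swc", "write_swc"]


class SWCFormatError(ValueError):
    """Malformed SWC content; the message names the offending line."""


def write_swc(tree: NeuronTree, path) -> None:
    """Export ``tree`` as a standard SWC file (ids contiguous from 1)."""
    tree.validate()
    lines = ["# generated by morphabc", "# id type x y z radius parent"]
    next_id = 1
    record_of: dict[int, int] = {}

    def emit(type_code, xyz, radius, parent_record):
        nonlocal next_id
        rid = next_id
        next_id += 1
        x, y, z = (float(c) for c in xyz)
        lines.append(
            f"{rid} {type_code} {x:.6f} {y:.6f} {z:.6f} {radius:.6f} {parent_record}"
        )
        return rid

    soma = tree.nodes[tree.soma_id]
    soma_rec = emit(1, tree.soma_position, tree.soma_radius, -1)

    # depth-first, children in id order, parents emitted before children
    stack = sorted(soma.children, reverse=True)
    while stack:
        nid = stack.pop()
        node = tree.nodes[nid]
        parent = tree.nodes[node.parent]
        parent_record = soma_rec if parent.kind == SOMA else record_of[node.parent]
        record_of[nid] = emit(node.subtype, node.end, node.diameter / 2.0, parent_record)
        stack.extend(sorted(node.children, reverse=True))

    Path(path).write_text("\n".join(lines) + "\n")


def read_swc(path) -> NeuronTree:
    """Parse an SWC file into a validated :class:`NeuronTree`."""
    records: dict[int, tuple[int, np.ndarray, float, int]] = {}
    order: list[int] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 7:
            raise SWCFormatError(f"line {lineno}: expected 7 columns, got {len(parts)}")
        try:
            rid = int(parts[0])
            type_code = int(parts[1])
            xyz = np.array([float(parts[2]), float(parts[3]), float(parts[4])])
            radius = float(parts[5])
            parent = int(parts[6])
        except ValueError as exc:
            raise SWCFormatError(f"line {lineno}: non-numeric field ({exc})") from None
        if rid in records:
            raise SWCFormatError(f"line {lineno}: duplicate id {rid}")
        if parent != -1 and parent not in records:
            raise SWCFormatError(
                f"line {lineno}: parent id {parent} not defined before child {rid}"
            )
        records[rid] = (type_code, xyz, radius, parent)
        order.append(rid)

    roots = [rid for rid in order if records[rid][3] == -1]
    if len(roots) != 1:
        raise SWCFormatError(f"expected exactly one root record, found {len(roots)}")
    root = roots[0]
    root_type, root_xyz, root_radius, _ = records[root]
    if root_type != 1:
        raise SWCFormatError(f"root record {root} is not of soma type (1)")

    tree = NeuronTree(soma_position=root_xyz, soma_radius=root_radius)
    # swc record id -> (agent id or soma, anchor point of the record)
    agent_of: dict[int, int] = {root: tree.soma_id}
    point_of: dict[int, np.ndarray] = {root: root_xyz}
    for rid in order:
        type_code, xyz, radius, parent = records[rid]
        if rid == root:
            continue
        if type_code == 1:
            # additional soma points are absorbed into the soma sphere
            agent_of[rid] = tree.soma_id
            point_of[rid] = xyz
            continue
        subtype = APICAL if type_code == 4 else BASAL
        p_agent = agent_of[parent]
        node = tree.add_node(
            kind=NEURITE,
            start=point_of[parent].copy(),
            end=xyz.copy(),
            diameter=2.0 * radius,
            parent=p_agent,
            subtype=subtype,
        )
        if node.length > 1e-12:
            node.orientation = (node.end - node.start) / node.length
        agent_of[rid] = node.id
        point_of[rid] = xyz
    tree.validate()
    return tree
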