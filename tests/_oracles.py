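"""Independent oracles used by the tests.

These deliberately avoid the code paths they check: substructure counts come
from a hand-rolled backtracking subgraph-isomorphism enumeration (using only
RDKit's per-atom/per-bond query predicates, not its matcher), and metrics
are computed from their textbook definitions.
"""

from __future__ import annotations

import numpy as np
from rdkit import Chem


def brute_force_match_sets(mol: Chem.Mol, query: Chem.Mol) -> set[frozenset]:
    """All distinct atom-index sets of `mol` matching the connected `query`.

    Backtracking over an order in which every query atom (after the first)
    is adjacent to an already-placed one; all query bonds between placed
    atoms are checked, so ring closures are honoured. Matches differing only
    by atom order collapse to one frozenset.
    """
    nq = query.GetNumAtoms()
    adj = {
        i: [n.GetIdx() for n in query.GetAtomWithIdx(i).GetNeighbors()]
        for i in range(nq)
    }
    # connected DFS order
    order, seen, stack = [], set(), [0]
    while stack:
        i = stack.pop()
        if i in seen:
            continue
        seen.add(i)
        order.append(i)
        stack.extend(j for j in adj[i] if j not in seen)
    assert len(order) == nq, "oracle requires a connected query"

    results: set[frozenset] = set()
    mapping: dict[int, int] = {}
    used: set[int] = set()

    def place(pos: int) -> None:
        if pos == nq:
            results.add(frozenset(mapping.values()))
            return
        qi = order[pos]
        placed_nbrs = [j for j in adj[qi] if j in mapping]
        if placed_nbrs:
            candidates = [
                n.GetIdx()
                for n in mol.GetAtomWithIdx(mapping[placed_nbrs[0]]).GetNeighbors()
            ]
        else:
            candidates = range(mol.GetNumAtoms())
        qatom = query.GetAtomWithIdx(qi)
        for t in candidates:
            if t in used or not qatom.Match(mol.GetAtomWithIdx(t)):
                continue
            ok = True
            for j in placed_nbrs:
                tb = mol.GetBondBetweenAtoms(t, mapping[j])
                if tb is None or not query.GetBondBetweenAtoms(qi, j).Match(tb):
                    ok = False
                    break
            if ok:
                mapping[qi] = t
                used.add(t)
                place(pos + 1)
                del mapping[qi]
                used.remove(t)

    place(0)
    return results


def brute_force_count(mol: Chem.Mol, smarts: str) -> int:
    query = Chem.MolFromSmarts(smarts)
    assert query is not None
    return len(brute_force_match_sets(mol, query))


# -- metric definitions from scratch ----------------------------------------

def manual_r2(y_true, y_pred) -> float:
    y_true = np.asarray(y_true, float)
    y_pred = np.asarray(y_pred, float)
    ss_res = np.sum((y_true - y_pred) ** 2)
    ss_tot = np.sum((y_true - y_true.mean()) ** 2)
    return 1.0 - ss_res / ss_tot


def manual_weighted_f1(y_true, y_pred, labels) -> float:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    total = 0.0
    for lab in labels:
        tp = np.sum((y_pred == lab) & (y_true == lab))
        fp = np.sum((y_pred == lab) & (y_true != lab))
        fn = np.sum((y_pred != lab) & (y_true == lab))
        support = np.sum(y_true == lab)
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        total += support * f1
    return total / len(y_true)


def trapezoid_path_integral_ig(model, x, baseline, n_steps, target=None):
    """Fine-discretization normalized IG oracle (independent trapezoid)."""
    x = np.asarray(x, float)
    baseline = np.asarray(baseline, float)
    alphas = np.linspace(0.0, 1.0, n_steps)
    grads = np.stack([
        model.input_gradient(baseline + a * (x - baseline), target=target)
        for a in alphas
    ])
    avg = np.trapezoid(grads, alphas, axis=0)
    return (x - baseline) * avg
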