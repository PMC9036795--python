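"""Exhaustive isotopomer balance oracle for small networks.

Solves the full positional isotopomer system (2^n states per n-carbon
metabolite) at isotopic steady state and collapses the result to MDVs.
The balance is bilinear in the unknowns (condensation products multiply
substrate distributions), so it is solved by damped fixed-point iteration
to machine precision rather than by a linear solve.  Intended purely as an
independent verification oracle for the EMU simulator; refuses networks
with more than 2^20 total isotopomer states.
"""

from __future__ import annotations

import numpy as np

from .correction import NATURAL_13C
from .emu import TracerSpec, _consumption_flux, _producer_instances
from .network import FluxVector, ReactionNetwork

_MAX_STATES = 2 ** 20


def _tracer_tensor(tracer: TracerSpec) -> np.ndarray:
    """Isotopomer distribution as a (2,)*n tensor; axis i = carbon i+1."""
    t = np.array([1.0])
    for e in tracer.enrichments:
        t = np.multiply.outer(t, np.array([1.0 - e, e]))
    return t[0] if t.ndim > len(tracer.enrichments) else t


def _collapse_to_mdv(tensor: np.ndarray) -> np.ndarray:
    n = tensor.ndim
    mdv = np.zeros(n + 1)
    flat = tensor.reshape(-1)
    for state, p in enumerate(flat):
        mdv[bin(state).count("1")] += p
    return mdv


def isotopomer_oracle(net: ReactionNetwork, v: FluxVector,
                      tracers: TracerSpec | list[TracerSpec],
                      targets: list[str],
                      natural: float = NATURAL_13C,
                      tol: float = 1e-14, max_iter: int = 100000,
                      ) -> dict[str, np.ndarray]:
    """Exact MDVs from the full isotopomer balance (small networks only)."""
    if isinstance(tracers, TracerSpec):
        tracers = [tracers]
    tracer_map = {t.substrate: t for t in tracers}
    balanced = [m for m in net.balanced if net.metabolites[m].n_carbons > 0]
    total_states = sum(2 ** net.metabolites[m].n_carbons for m in balanced)
    if total_states > _MAX_STATES:
        raise ValueError(f"network too large for the isotopomer oracle "
                         f"({total_states} states); use the EMU simulator")
    producers = _producer_instances(net)
    vf, vb = v.forward_backward(net)
    idx = net.reaction_index
    cons = _consumption_flux(net, vf, vb)

    def external_tensor(met: str) -> np.ndarray:
        tracer = tracer_map.get(met)
        if tracer is None:
            tracer = TracerSpec.positional(
                met, net.metabolites[met].n_carbons, {}, natural=natural)
        return _tracer_tensor(tracer)

    # state: tensor of shape (2,)*n per balanced metabolite
    state = {m: _tracer_tensor(TracerSpec.positional(
        m, net.metabolites[m].n_carbons, {}, natural=0.0)) for m in balanced}

    def tensor_of(met: str) -> np.ndarray:
        return external_tensor(met) if net.metabolites[met].external else state[met]

    for _ in range(max_iter):
        delta = 0.0
        new_state = {}
        for met in balanced:
            c = cons.get(met, 0.0)
            if c <= 1e-15:
                raise ValueError(f"metabolite {met}: zero consumption flux")
            n = net.metabolites[met].n_carbons
            acc = np.zeros((2,) * n)
            for inst in producers.get(met, []):
                flux = (vf if inst.direction == "fwd" else vb)[idx[inst.reaction_id]]
                if flux <= 0.0:
                    continue
                # joint distribution over product atoms: outer product of the
                # used-atom marginals of each source, axes reordered to the
                # product's carbon order
                by_term: dict[int, list[tuple[int, int, str]]] = {}
                for ppos, (src_met, src_term, src_pos) in enumerate(
                        inst.atom_origin, start=1):
                    by_term.setdefault(src_term, []).append((ppos, src_pos, src_met))
                joint = np.array(1.0)
                axis_targets: list[int] = []  # product position per joint axis
                for src_term in sorted(by_term):
                    entries = by_term[src_term]
                    src_met = entries[0][2]
                    src_t = tensor_of(src_met)
                    used = sorted(src_pos for _, src_pos, _ in entries)
                    drop = tuple(ax for ax in range(src_t.ndim)
                                 if (ax + 1) not in used)
                    marg = src_t.sum(axis=drop) if drop else src_t
                    # marg axes follow ascending src position order
                    src_to_ppos = {src_pos: ppos for ppos, src_pos, _ in entries}
                    joint = np.multiply.outer(joint, marg)
                    axis_targets.extend(src_to_ppos[p] for p in used)
                joint = joint.reshape([2] * n)
                joint = np.moveaxis(joint, range(n),
                                    [t - 1 for t in axis_targets])
                acc += flux * joint
            new = acc / c
            delta = max(delta, float(np.max(np.abs(new - state[met]))))
            new_state[met] = new
        state = new_state
        if delta < tol:
            break
    else:
        raise RuntimeError("isotopomer fixed point did not converge")
    out = {}
    for t in targets:
        tensor = tensor_of(t)
        out[t] = _collapse_to_mdv(tensor)
    return out
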