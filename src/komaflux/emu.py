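"""Steady-state 13C labeling simulation via EMU decomposition.

An EMU (elementary metabolite unit) is a subset of a metabolite's carbon
atoms.  The mass isotopologue distribution (MDV) of an EMU of size k obeys a
linear balance at isotopic steady state:

    (total consumption flux of M) * x_EMU = sum_producers flux * x_source

where the source of a producer is either a single EMU of the same size or the
convolution of smaller EMUs (condensation reactions).  Decomposing backward
from the measured targets yields the minimal EMU set, layered by size; each
layer is a dense linear solve.

Reversible reactions contribute both directions, with forward flux
net+ + exchange and backward flux net- + exchange.  Simulated MDVs cover the
carbon backbone only; derivatization atoms are handled in the correction
module.  Natural 13C abundance at unlabeled substrate positions is included
by default so simulated backbone MDVs are directly comparable to corrected
measured CIDs.
"""

from __future__ import annotations

import dataclasses
import itertools
from collections import defaultdict

import numpy as np

from .correction import NATURAL_13C
from .network import FluxVector, ReactionNetwork

EmuKey = tuple[str, tuple[int, ...]]  # (metabolite, 1-based carbon positions)


@dataclasses.dataclass
class TracerSpec:
    """Positional 13C enrichment of a fed substrate.

    ``enrichments[i]`` is the 13C fraction at carbon i+1.  Unlabeled positions
    default to natural abundance.  For 1-13C xylose at isotopic purity p:
    position 1 = p, positions 2-5 = 0.0107.
    """

    substrate: str
    enrichments: np.ndarray

    def __post_init__(self) -> None:
        self.enrichments = np.asarray(self.enrichments, dtype=float)
        if np.any((self.enrichments < 0) | (self.enrichments > 1)):
            raise ValueError("enrichments must be fractions in [0, 1]")

    @classmethod
    def positional(cls, substrate: str, n_carbons: int,
                   labeled: dict[int, float],
                   natural: float = NATURAL_13C) -> "TracerSpec":
        e = np.full(n_carbons, natural)
        for pos, frac in labeled.items():
            if not 1 <= pos <= n_carbons:
                raise ValueError(f"position {pos} outside 1..{n_carbons}")
            e[pos - 1] = frac
        return cls(substrate, e)

    def emu_mdv(self, positions: tuple[int, ...]) -> np.ndarray:
        out = np.array([1.0])
        for pos in positions:
            e = self.enrichments[pos - 1]
            out = np.convolve(out, np.array([1.0 - e, e]))
        return out


def one_13c_xylose(purity: float = 0.99,
                   natural: float = NATURAL_13C) -> TracerSpec:
    """The study's tracer: 1-13C D-xylose fed as XYL_ext."""
    return TracerSpec.positional("XYL_ext", 5, {1: purity}, natural=natural)


@dataclasses.dataclass
class _ProducerInstance:
    """One atom-mapped way a reaction (in one direction) produces a metabolite."""

    reaction_id: str
    direction: str  # "fwd" | "bwd"
    # for each product carbon position (1-based): (source metabolite, source position)
    atom_origin: list[tuple[str, int, int]]  # (src met, src term index, src position)


def _producer_instances(net: ReactionNetwork) -> dict[str, list[_ProducerInstance]]:
    """All atom-mapped producer instances per metabolite."""
    producers: dict[str, list[_ProducerInstance]] = defaultdict(list)
    for rxn in net.reactions:
        if rxn.rtype == "B":
            continue
        directions = [("fwd", rxn.substrates, rxn.products)]
        if rxn.reversible:
            directions.append(("bwd", rxn.products, rxn.substrates))
        for direction, subs, prods in directions:
            letter_origin: dict[str, tuple[str, int, int]] = {}
            for ti, term in enumerate(subs):
                if term.atoms:
                    for pos, letter in enumerate(term.atoms, start=1):
                        letter_origin[letter] = (term.metabolite, ti, pos)
            for term in prods:
                if not term.atoms or net.metabolites[term.metabolite].external:
                    continue
                origin = [letter_origin[letter] for letter in term.atoms]
                producers[term.metabolite].append(
                    _ProducerInstance(rxn.id, direction, origin))
    return dict(producers)


def _consumption_flux(net: ReactionNetwork, vf: np.ndarray,
                      vb: np.ndarray) -> dict[str, float]:
    cons: dict[str, float] = defaultdict(float)
    for i, rxn in enumerate(net.reactions):
        for term in rxn.substrates:
            cons[term.metabolite] += term.coef * vf[i]
        if rxn.reversible:
            for term in rxn.products:
                cons[term.metabolite] += term.coef * vb[i]
    return cons


@dataclasses.dataclass
class EmuEdge:
    reaction_id: str
    direction: str
    parts: list[EmuKey]  # each (metabolite, positions); convolution if > 1


@dataclasses.dataclass
class EmuNetwork:
    """Backward-reachable EMU set with producer edges, layered by size."""

    net: ReactionNetwork
    edges: dict[EmuKey, list[EmuEdge]]
    sizes: dict[int, list[EmuKey]]  # internal EMUs per size, solve order

    def n_emus(self) -> int:
        return sum(len(v) for v in self.sizes.values())


def emu_decompose(net: ReactionNetwork, targets: list[str]) -> EmuNetwork:
    """Minimal EMU network reachable backward from the target metabolites."""
    for t in targets:
        if t not in net.metabolites:
            raise ValueError(f"target {t} not in network")
        if net.metabolites[t].n_carbons < 1:
            raise ValueError(f"target {t} has no carbon atoms")
    producers = _producer_instances(net)
    edges: dict[EmuKey, list[EmuEdge]] = {}
    queue: list[EmuKey] = [
        (t, tuple(range(1, net.metabolites[t].n_carbons + 1))) for t in targets]
    while queue:
        emu = queue.pop()
        if emu in edges:
            continue
        met, positions = emu
        if net.metabolites[met].external:
            continue
        if met not in producers:
            raise ValueError(f"metabolite {met} has no atom-mapped producer")
        emu_edges = []
        for inst in producers[met]:
            grouped: dict[int, list[tuple[int, str]]] = defaultdict(list)
            for pos in positions:
                src_met, src_term, src_pos = inst.atom_origin[pos - 1]
                grouped[src_term].append((src_pos, src_met))
            parts: list[EmuKey] = []
            for src_term in sorted(grouped):
                src_positions = tuple(sorted(p for p, _ in grouped[src_term]))
                src_met = grouped[src_term][0][1]
                parts.append((src_met, src_positions))
            emu_edges.append(EmuEdge(inst.reaction_id, inst.direction, parts))
            for part in parts:
                if not net.metabolites[part[0]].external and part not in edges:
                    queue.append(part)
        edges[emu] = emu_edges
    sizes: dict[int, list[EmuKey]] = defaultdict(list)
    for emu in edges:
        sizes[len(emu[1])].append(emu)
    return EmuNetwork(net, edges, {k: sorted(v) for k, v in sorted(sizes.items())})


def simulate_mdv(net: ReactionNetwork, v: FluxVector,
                 tracers: TracerSpec | list[TracerSpec],
                 targets: list[str],
                 natural: float = NATURAL_13C,
                 emu_net: EmuNetwork | None = None,
                 dilution: float = 0.0) -> dict[str, np.ndarray]:
    """Steady-state carbon-backbone MDVs of the target metabolites.

    External substrates without an explicit tracer sit at ``natural``
    abundance on every position (set natural=0 for idealized simulations).

    ``dilution`` adds an infinitesimal natural-background exchange flux to
    every pool's balance.  With the default 0 the balances are exact and a
    pool with strictly zero turnover falls back discretely to natural
    background; a small positive value (used by the flux fitter) makes the
    simulated MDVs continuous in the fluxes at negligible bias for any pool
    whose turnover far exceeds it.
    """
    if isinstance(tracers, TracerSpec):
        tracers = [tracers]
    tracer_map = {t.substrate: t for t in tracers}
    if emu_net is None:
        emu_net = emu_decompose(net, targets)
    vf, vb = v.forward_backward(net)
    idx = net.reaction_index
    cons = _consumption_flux(net, vf, vb)
    solved: dict[EmuKey, np.ndarray] = {}

    def known_mdv(emu: EmuKey) -> np.ndarray:
        met, positions = emu
        if net.metabolites[met].external:
            tracer = tracer_map.get(met)
            if tracer is None:
                tracer = TracerSpec.positional(
                    met, net.metabolites[met].n_carbons, {}, natural=natural)
            return tracer.emu_mdv(positions)
        return solved[emu]

    for size, emus in emu_net.sizes.items():
        index = {emu: i for i, emu in enumerate(emus)}
        n = len(emus)
        A = np.zeros((n, n))
        B = np.zeros((n, size + 1))
        natural_bg = TracerSpec.positional(
            "_bg", size, {}, natural=natural).emu_mdv(
                tuple(range(1, size + 1)))
        for emu, i in index.items():
            met = emu[0]
            c = cons.get(met, 0.0) + dilution
            if c <= 1e-12:
                # zero-turnover pool (e.g. 6-phosphogluconate when the
                # oxidative PPP carries no flux): the pool still exists and
                # sits at natural background labeling
                producing = [e for e in emu_net.edges[emu]
                             if (vf if e.direction == "fwd" else vb)[
                                 idx[e.reaction_id]] > 1e-12]
                if producing:
                    raise ValueError(
                        f"EMU {met}{list(emu[1])}: produced but never consumed "
                        "at this flux vector")
                A[i, i] = 1.0
                B[i, :] = natural_bg
                continue
            A[i, i] = c
            B[i, :] += dilution * natural_bg
            for edge in emu_net.edges[emu]:
                flux = (vf if edge.direction == "fwd" else vb)[idx[edge.reaction_id]]
                if flux <= 0.0:
                    continue
                if (len(edge.parts) == 1
                        and not net.metabolites[edge.parts[0][0]].external
                        and len(edge.parts[0][1]) == size):
                    A[i, index[edge.parts[0]]] -= flux
                else:
                    mdv = np.array([1.0])
                    for part in edge.parts:
                        mdv = np.convolve(mdv, known_mdv(part))
                    B[i, :] += flux * mdv
        try:
            X = np.linalg.solve(A, B)
        except np.linalg.LinAlgError as exc:
            raise ValueError(f"singular EMU balance at size {size}: {exc}") from exc
        for emu, i in index.items():
            x = np.clip(X[i], 0.0, None)
            total = x.sum()
            if not np.isfinite(total) or total <= 0:
                raise ValueError(f"EMU {emu}: degenerate MDV")
            solved[emu] = x / total
    out = {}
    for t in targets:
        key = (t, tuple(range(1, net.metabolites[t].n_carbons + 1)))
        out[t] = solved[key] if key in solved else known_mdv(key)
    return out
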