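"""Stoichiometric reaction network with carbon atom transitions.

The model CSV dialect has columns ``id, equation, reversible, type, block,
alias``.  Equations look like::

    OAA (abcd) + ACA (ef) -> CIT (dcbfea)
    0.3 G6P + 0.12 R5P -> BIOMASS

Atom transitions are letter codes per metabolite occurrence: every letter is
unique within one side of the equation and the multiset of letters must be
conserved across sides (carbon conservation).  Reactions of type ``B``
(biomass/drain) carry no atom map; they only consume and never produce
balanced metabolites, so they never enter labeling balances as producers.
Metabolites whose id ends in ``_ext`` (plus the BIOMASS pseudo-metabolite)
are external and excluded from the steady-state balance S v = 0.

Reversible reactions are parameterized as net + exchange fluxes:
forward = max(net, 0) + exchange, backward = max(-net, 0) + exchange.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import re
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.optimize

_TERM_RE = re.compile(
    r"^\s*(?:(\d+(?:\.\d+)?)\s+)?([A-Za-z][A-Za-z0-9_]*)\s*(?:\(([A-Za-z]+)\))?\s*$")


@dataclasses.dataclass
class Term:
    metabolite: str
    coef: float
    atoms: str | None  # letter code, one letter per carbon


@dataclasses.dataclass
class Reaction:
    id: str
    substrates: list[Term]
    products: list[Term]
    reversible: bool
    rtype: str = "N"          # N = normal, B = biomass/drain (no atom map)
    block: str = "base_model"
    alias: str | None = None

    def carbon_letters(self, side: str) -> list[str]:
        terms = self.substrates if side == "sub" else self.products
        letters: list[str] = []
        for t in terms:
            if t.atoms:
                letters.extend(t.atoms)
        return letters


@dataclasses.dataclass
class Metabolite:
    id: str
    n_carbons: int
    external: bool


def _parse_side(side: str) -> list[Term]:
    terms = []
    for token in side.split("+"):
        m = _TERM_RE.match(token)
        if m is None:
            raise ValueError(f"cannot parse equation term {token!r}")
        coef = float(m.group(1)) if m.group(1) else 1.0
        terms.append(Term(m.group(2), coef, m.group(3)))
    return terms


def parse_equation(equation: str) -> tuple[list[Term], list[Term]]:
    for arrow in ("<->", "->", "="):
        if arrow in equation:
            left, right = equation.split(arrow, 1)
            return _parse_side(left), _parse_side(right)
    raise ValueError(f"no arrow in equation {equation!r}")


def _is_external(met_id: str) -> bool:
    return met_id.endswith("_ext") or met_id == "BIOMASS"


class ReactionNetwork:
    def __init__(self, reactions: list[Reaction]):
        self.reactions = reactions
        self.reaction_index = {r.id: i for i, r in enumerate(reactions)}
        if len(self.reaction_index) != len(reactions):
            seen, dup = set(), None
            for r in reactions:
                if r.id in seen:
                    dup = r.id
                seen.add(r.id)
            raise ValueError(f"duplicate reaction id: {dup}")
        self.metabolites = self._collect_metabolites()
        self.balanced = [m for m in sorted(self.metabolites)
                         if not self.metabolites[m].external]

    def _collect_metabolites(self) -> dict[str, Metabolite]:
        mets: dict[str, Metabolite] = {}
        for rxn in self.reactions:
            for term in rxn.substrates + rxn.products:
                nc = len(term.atoms) if term.atoms else 0
                if term.metabolite in mets:
                    prev = mets[term.metabolite]
                    if term.atoms and prev.n_carbons and nc != prev.n_carbons:
                        raise ValueError(
                            f"{rxn.id}: {term.metabolite} has {nc} carbons here "
                            f"but {prev.n_carbons} elsewhere")
                    if term.atoms and not prev.n_carbons:
                        prev.n_carbons = nc
                else:
                    mets[term.metabolite] = Metabolite(
                        term.metabolite, nc, _is_external(term.metabolite))
        return mets

    # -- stoichiometry ------------------------------------------------------

    def stoich_matrix(self) -> pd.DataFrame:
        """S over balanced metabolites x reactions."""
        S = pd.DataFrame(0.0, index=self.balanced,
                         columns=[r.id for r in self.reactions])
        for rxn in self.reactions:
            for term in rxn.substrates:
                if term.metabolite in S.index:
                    S.loc[term.metabolite, rxn.id] -= term.coef
            for term in rxn.products:
                if term.metabolite in S.index:
                    S.loc[term.metabolite, rxn.id] += term.coef
        return S

    @property
    def reversible_ids(self) -> list[str]:
        return [r.id for r in self.reactions if r.reversible]

    def degrees_of_freedom(self) -> int:
        S = self.stoich_matrix().to_numpy()
        return S.shape[1] - np.linalg.matrix_rank(S)

    def block(self, name: str) -> list[Reaction]:
        return [r for r in self.reactions if r.block == name]

    # -- validation ---------------------------------------------------------

    def validate(self) -> list[str]:
        """Return a list of violation messages (empty = valid)."""
        issues: list[str] = []
        for rxn in self.reactions:
            if rxn.rtype == "B":
                continue
            sub = rxn.carbon_letters("sub")
            prod = rxn.carbon_letters("prod")
            if len(set(sub)) != len(sub):
                issues.append(f"{rxn.id}: duplicate atom letter on substrate side")
            if len(set(prod)) != len(prod):
                issues.append(f"{rxn.id}: duplicate atom letter on product side")
            if sorted(sub) != sorted(prod):
                issues.append(f"{rxn.id}: carbon letters not conserved "
                              f"({''.join(sorted(sub))} vs {''.join(sorted(prod))})")
            for term in rxn.substrates + rxn.products:
                if term.atoms is None and not _is_external(term.metabolite):
                    issues.append(f"{rxn.id}: balanced metabolite "
                                  f"{term.metabolite} lacks an atom map")
                if term.atoms is not None and term.coef != 1.0:
                    issues.append(f"{rxn.id}: atom-mapped term {term.metabolite} "
                                  f"must have coefficient 1")
        produced, consumed = set(), set()
        for rxn in self.reactions:
            for term in rxn.substrates:
                consumed.add(term.metabolite)
                if rxn.reversible:
                    produced.add(term.metabolite)
            for term in rxn.products:
                produced.add(term.metabolite)
                if rxn.reversible:
                    consumed.add(term.metabolite)
        for met in self.balanced:
            if met not in produced:
                issues.append(f"metabolite {met} is never produced")
            if met not in consumed:
                issues.append(f"metabolite {met} is never consumed")
        return issues

    def validation_report(self) -> dict:
        S = self.stoich_matrix().to_numpy()
        rank = int(np.linalg.matrix_rank(S))
        return {
            "violations": self.validate(),
            "n_reactions": len(self.reactions),
            "n_balanced_metabolites": len(self.balanced),
            "rank": rank,
            "degrees_of_freedom": S.shape[1] - rank,
        }


@dataclasses.dataclass
class FluxVector:
    """Net fluxes per reaction plus nonnegative exchange fluxes for reversibles.

    Units follow the uptake normalization (mmol g^-1 h^-1 when the uptake is
    fixed to a measured specific rate, dimensionless when fixed to 1).
    """

    reaction_ids: list[str]
    net: np.ndarray
    exchange: np.ndarray  # same length; nonzero only for reversible reactions

    def __getitem__(self, rid: str) -> float:
        return float(self.net[self.reaction_ids.index(rid)])

    def forward_backward(self, net_obj: "ReactionNetwork") -> tuple[np.ndarray, np.ndarray]:
        vf = np.maximum(self.net, 0.0) + self.exchange
        vb = np.maximum(-self.net, 0.0) + self.exchange
        return vf, vb

    def as_series(self) -> pd.Series:
        return pd.Series(self.net, index=self.reaction_ids, name="net_flux")


def per_carbon_rates(net: ReactionNetwork, v: FluxVector) -> pd.Series:
    """Specific rate per carbon atom: molar net flux x carbons transferred."""
    rates = {}
    for rxn in net.reactions:
        carbons = sum(len(t.atoms) for t in rxn.substrates if t.atoms)
        if carbons == 0 and rxn.rtype == "B":
            carbons = sum(t.coef * net.metabolites[t.metabolite].n_carbons
                          for t in rxn.substrates)
        rates[rxn.id] = v[rxn.id] * carbons
    return pd.Series(rates, name="per_carbon_rate")


# ---------------------------------------------------------------------------
# model IO

def read_model(path: str | Path) -> ReactionNetwork:
    """Read a model CSV (columns: id, equation, reversible, type, block, alias)."""
    df = pd.read_csv(path, comment="#")
    required = {"id", "equation", "reversible"}
    if not required.issubset(df.columns):
        raise ValueError(f"model CSV missing columns: "
                         f"{sorted(required - set(df.columns))}")
    reactions = []
    for _, row in df.iterrows():
        subs, prods = parse_equation(str(row["equation"]))
        reactions.append(Reaction(
            id=str(row["id"]), substrates=subs, products=prods,
            reversible=bool(int(row["reversible"])),
            rtype=str(row.get("type", "N")) if pd.notna(row.get("type")) else "N",
            block=str(row.get("block", "base_model"))
            if pd.notna(row.get("block")) else "base_model",
            alias=str(row["alias"]) if "alias" in df.columns
            and pd.notna(row["alias"]) else None,
        ))
    network = ReactionNetwork(reactions)
    issues = [v for v in network.validate() if "never" not in v]
    if issues:
        raise ValueError("invalid model: " + "; ".join(issues))
    return network


def load_fixture_model() -> ReactionNetwork:
    """The packaged central-carbon + xylose-oxidoreductase model.

    A reconstruction of the study's stoichiometric model: non-oxidative and
    oxidative pentose phosphate pathway, upper glycolysis run gluconeogenically
    to G6P and glucose, lower glycolysis to pyruvate, a compact TCA cycle, a
    lumped biomass drain, and the five-reaction xylose extension (xylose
    uptake, xylose reductase, xylitol dehydrogenase, xylulokinase, xylitol
    efflux; aliases R48, R49, R50, R59, R25).
    """
    ref = importlib.resources.files("komaflux.data") / "central_carbon_xylose.csv"
    with importlib.resources.as_file(ref) as p:
        return read_model(p)


# ---------------------------------------------------------------------------
# feasible flux sampling

def sample_feasible_flux(net: ReactionNetwork,
                         constraints: dict[str, float] | None = None,
                         bounds: dict[str, tuple[float, float]] | None = None,
                         exchange: dict[str, float] | float = 0.0,
                         rng_seed: int = 0,
                         flux_cap: float = 100.0) -> FluxVector:
    """A deterministic feasible flux vector: S v = 0, constraints and bounds met.

    ``constraints`` fixes net fluxes by reaction id; ``exchange`` sets exchange
    fluxes for reversible reactions (scalar or per-id dict).  The vertex
    returned is selected by a seeded random linear objective, so the same seed
    always yields the same vector.
    """
    constraints = constraints or {}
    bounds = bounds or {}
    S = net.stoich_matrix()
    n = len(net.reactions)
    lb = np.zeros(n)
    ub = np.full(n, flux_cap)
    for i, rxn in enumerate(net.reactions):
        if rxn.reversible:
            lb[i] = -flux_cap
        rid = rxn.id
        if rid in bounds:
            lb[i], ub[i] = bounds[rid]
        if rid in constraints:
            lb[i] = ub[i] = constraints[rid]
    unknown = set(constraints) - set(net.reaction_index)
    if unknown:
        raise ValueError(f"constraints on unknown reactions: {sorted(unknown)}")
    rng = np.random.default_rng(rng_seed)
    c = rng.uniform(0.01, 1.0, n)
    res = scipy.optimize.linprog(c, A_eq=S.to_numpy(), b_eq=np.zeros(len(S)),
                                 bounds=list(zip(lb, ub)), method="highs")
    if not res.success:
        raise ValueError(f"infeasible flux constraints: {res.message}")
    exch = np.zeros(n)
    for i, rxn in enumerate(net.reactions):
        if rxn.reversible:
            exch[i] = (exchange.get(rxn.id, 0.0)
                       if isinstance(exchange, dict) else float(exchange))
    v = np.where(np.abs(res.x) < 1e-12, 0.0, res.x)
    return FluxVector([r.id for r in net.reactions], v, exch)
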