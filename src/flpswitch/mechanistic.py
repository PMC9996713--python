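"""Full mechanistic reaction network of the inversion-excision switch.

The switch couples four site-specific recombination events: two reversible
inversions (``i1``: S1 -> tS1, ``i2``: S1 -> tS2) and two quasi-stable
excisions (``e1``: tS1 -> S2 + SX, ``e2``: tS2 -> S2 + SX).  Each event is
resolved into its molecular steps:

* a cooperative FlpO monomer-binding cascade on the substrate DNA
  (free -> F1 -> {F1,1 | F2,0} -> F3 -> F4, i.e. up to two monomers on each
  of the two FRT attachment sites),
* entry into a ladder of five sequential Holliday-junction complexes
  (strand exchanges k4..k7 with reverses; entry/exit at k3/k-3, and for the
  excision product side resolution/re-association at k8/k-8),
* dissociation of the product complexes back to free, genetically
  differentiated DNA.

Events sharing an FRT attachment-site pair share binding constants:
``i1``/``e2`` use pair A and ``i2``/``e1`` use pair B.  Positive binding
cooperativity is imposed through multipliers ``0 < m1, m2 < 1``: a monomer
binds a free site at ``m1*k_on`` and leaves it at ``k_off``, but binds an
already-occupied site at ``k_on`` and leaves it at ``m2*k_off``, which
guarantees the affinity ordering k1/k-1 < k2/k-2.

The network is pure mass action: every reaction is at most bimolecular, and
the right-hand side is the stoichiometry matrix applied to the flux vector.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, fields
from typing import Sequence

import numpy as np

__all__ = [
    "MechanisticParameters",
    "Species",
    "Reaction",
    "ReactionNetwork",
    "FITTED_MECHANISTIC_NAMES",
    "effective_binding_rates",
    "build_mechanistic_network",
    "mass_action_rhs",
    "state_totals",
    "mechanistic_initial_state",
]

#: the 27 rate constants subject to inference (alpha_d and vbar excluded)
FITTED_MECHANISTIC_NAMES = (
    "alpha_a", "alpha_b", "beta_p", "beta_d", "K_a", "K_b",
    "pairA_k_on", "pairA_k_off", "pairA_m1", "pairA_m2",
    "pairB_k_on", "pairB_k_off", "pairB_m1", "pairB_m2",
    "k3", "k3_rev", "k4", "k4_rev", "k5", "k5_rev",
    "k6", "k6_rev", "k7", "k7_rev", "k8", "k8_rev",
    "delta",
)


@dataclass(frozen=True)
class MechanisticParameters:
    """Rate constants of the full mechanistic model (a.u. / day units)."""

    alpha_a: float
    alpha_b: float
    beta_p: float
    beta_d: float
    K_a: float
    K_b: float
    pairA_k_on: float
    pairA_k_off: float
    pairA_m1: float
    pairA_m2: float
    pairB_k_on: float
    pairB_k_off: float
    pairB_m1: float
    pairB_m2: float
    k3: float
    k3_rev: float
    k4: float
    k4_rev: float
    k5: float
    k5_rev: float
    k6: float
    k6_rev: float
    k7: float
    k7_rev: float
    k8: float
    k8_rev: float
    delta: float
    alpha_d: float = 0.0
    vbar: float = 0.3

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"parameter {f.name}={v!r} must be finite and >= 0")
        for pair in ("pairA", "pairB"):
            for m in ("m1", "m2"):
                v = getattr(self, f"{pair}_{m}")
                if not 0.0 < v < 1.0:
                    raise ValueError(
                        f"cooperativity multiplier {pair}_{m}={v} must lie in (0, 1)"
                    )

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def effective_binding_rates(pair_k_on, pair_k_off, m1, m2):
    """Cooperative binding constants derived from one (k_on, k_off, m1, m2) set.

    Returns ``((k_on_free, k_off_free), (k_on_occ, k_off_occ))`` where the
    free-site pair is (m1*k_on, k_off) and the occupied-site pair is
    (k_on, m2*k_off).  With 0 < m1, m2 < 1 this enforces the cooperativity
    inequality k_on_free/k_off_free < k_on_occ/k_off_occ.
    """
    if not (0.0 < m1 < 1.0 and 0.0 < m2 < 1.0):
        raise ValueError("cooperativity multipliers must lie strictly in (0, 1)")
    if pair_k_on < 0 or pair_k_off < 0:
        raise ValueError("base binding rates must be >= 0")
    return (m1 * pair_k_on, pair_k_off), (pair_k_on, m2 * pair_k_off)


# --- species -----------------------------------------------------------------

FREE_DNA_TAGS = ("S1", "tS1", "tS2", "S2", "SX")
HJ_TAGS = ("HJ1", "HJ2", "HJ3", "HJ4", "HJ5")
PROTEIN_TAGS = ("F", "Fa", "Fb", "OHT")


@dataclass(frozen=True)
class Species:
    """One molecular entity: free DNA state, DNA:protein complex, or protein/drug.

    ``pathway`` names the recombination sub-network a complex belongs to
    (free states and proteins carry ``None``); ``state_tag`` is the genetic
    state of the DNA (or HJ1..HJ5 for junction complexes, or the protein
    name); ``occupancy`` counts bound FlpO monomers per attachment site.
    """

    pathway: str | None
    state_tag: str
    occupancy: str  # free | F1 | F1_1 | F2_0 | F3 | F4 | F2
    carries_promoter_strand: bool
    carries_blank_unit: bool

    @property
    def name(self) -> str:
        if self.pathway is None:
            return self.state_tag
        return f"{self.pathway}.{self.state_tag}.{self.occupancy}"

    @property
    def is_dna(self) -> bool:
        return self.state_tag not in PROTEIN_TAGS

    @property
    def bound_monomers(self) -> int:
        return {"free": 0, "F1": 1, "F1_1": 2, "F2_0": 2, "F3": 3, "F4": 4,
                "F2": 2}[self.occupancy]


@dataclass(frozen=True)
class Reaction:
    """Elementary (at most bimolecular) mass-action reaction.

    ``rate_ref`` names an entry of the network's rate-value table; the table
    in turn records which fitted parameters the value derives from.
    ``monomer_delta`` is the signed number of free FlpO monomers released
    (positive) or consumed (negative).
    """

    name: str
    reactants: tuple[tuple[str, int], ...]
    products: tuple[tuple[str, int], ...]
    rate_ref: str

    @property
    def monomer_delta(self) -> int:
        out = sum(n for s, n in self.products if s == "F")
        inn = sum(n for s, n in self.reactants if s == "F")
        return out - inn


class ReactionNetwork:
    """Species + reactions + rate bindings, with a cached stoichiometry matrix."""

    def __init__(self, species: Sequence[Species], reactions: Sequence[Reaction],
                 rate_values: dict[str, float], rate_fitted_deps: dict[str, tuple],
                 params: MechanisticParameters):
        self.species = list(species)
        self.reactions = list(reactions)
        self.rate_values = dict(rate_values)
        self.rate_fitted_deps = dict(rate_fitted_deps)
        self.params = params
        self.index = {s.name: i for i, s in enumerate(self.species)}
        if len(self.index) != len(self.species):
            raise ValueError("duplicate species names in network")
        self._stoich = None
        self._rates = None
        for rxn in self.reactions:
            for s, _ in rxn.reactants + rxn.products:
                if s not in self.index:
                    raise ValueError(f"reaction {rxn.name} references unknown species {s}")
            if rxn.rate_ref not in self.rate_values:
                raise ValueError(f"reaction {rxn.name} references unknown rate {rxn.rate_ref}")

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def dna_species(self) -> list[Species]:
        return [s for s in self.species if s.is_dna]

    @property
    def fitted_parameter_names(self) -> set[str]:
        """Distinct fitted rate-constant names referenced by the reactions."""
        used = set()
        for rxn in self.reactions:
            used.update(self.rate_fitted_deps[rxn.rate_ref])
        return used

    @property
    def stoichiometry_matrix(self) -> np.ndarray:
        if self._stoich is None:
            S = np.zeros((self.n_species, len(self.reactions)))
            for j, rxn in enumerate(self.reactions):
                for s, n in rxn.reactants:
                    S[self.index[s], j] -= n
                for s, n in rxn.products:
                    S[self.index[s], j] += n
            self._stoich = S
        return self._stoich

    @property
    def rate_vector(self) -> np.ndarray:
        if self._rates is None:
            self._rates = np.array(
                [self.rate_values[r.rate_ref] for r in self.reactions])
        return self._rates

    def flux_vector(self, state: np.ndarray) -> np.ndarray:
        flux = self.rate_vector.copy()
        for j, rxn in enumerate(self.reactions):
            for s, n in rxn.reactants:
                c = state[self.index[s]]
                flux[j] *= c if n == 1 else c ** n
        return flux

    def promoter_strand_mask(self) -> np.ndarray:
        return np.array([s.is_dna and s.carries_promoter_strand for s in self.species])

    def blank_unit_mask(self) -> np.ndarray:
        return np.array([s.is_dna and s.carries_blank_unit for s in self.species])

    def to_json(self) -> str:
        """Serialize the network structure for inspection / regression tests."""
        return json.dumps({
            "species": [{
                "name": s.name, "pathway": s.pathway, "state_tag": s.state_tag,
                "occupancy": s.occupancy,
                "carries_promoter_strand": s.carries_promoter_strand,
                "carries_blank_unit": s.carries_blank_unit,
            } for s in self.species],
            "reactions": [{
                "name": r.name,
                "reactants": [list(x) for x in r.reactants],
                "products": [list(x) for x in r.products],
                "rate_ref": r.rate_ref,
                "monomer_delta": r.monomer_delta,
            } for r in self.reactions],
            "rate_values": self.rate_values,
        }, indent=1, sort_keys=True)


# --- construction ------------------------------------------------------------

# (pathway, substrate, products, attachment-site pair, is_excision)
_EVENTS = (
    ("i1", "S1", ("tS1",), "pairA", False),
    ("i2", "S1", ("tS2",), "pairB", False),
    ("e1", "tS1", ("S2", "SX"), "pairB", True),
    ("e2", "tS2", ("S2", "SX"), "pairA", True),
)

# substrate-side cooperative cascade: (from_occ, to_occ, on_ref_kind, off_ref_kind)
_CASCADE = (
    ("free", "F1", "on_free", "off_free"),
    ("F1", "F1_1", "on_free", "off_free"),
    ("F1", "F2_0", "on_occ", "off_occ"),
    ("F1_1", "F3", "on_occ", "off_occ"),
    ("F2_0", "F3", "on_free", "off_free"),
    ("F3", "F4", "on_occ", "off_occ"),
)


def build_mechanistic_network(params: MechanisticParameters) -> ReactionNetwork:
    """Enumerate all species and elementary reactions of the full switch model.

    Construction is total for any valid parameter set; the resulting network
    has 63 DNA-containing species, four protein/drug species and references
    exactly 27 fitted rate constants.
    """
    p = params
    rate_values: dict[str, float] = {}
    deps: dict[str, tuple] = {}

    def bind(ref, value, *fitted):
        rate_values[ref] = value
        deps[ref] = tuple(fitted)

    for pair in ("pairA", "pairB"):
        k_on = getattr(p, f"{pair}_k_on")
        k_off = getattr(p, f"{pair}_k_off")
        m1 = getattr(p, f"{pair}_m1")
        m2 = getattr(p, f"{pair}_m2")
        (on_f, off_f), (on_o, off_o) = effective_binding_rates(k_on, k_off, m1, m2)
        bind(f"{pair}_on_free", on_f, f"{pair}_k_on", f"{pair}_m1")
        bind(f"{pair}_off_free", off_f, f"{pair}_k_off")
        bind(f"{pair}_on_occ", on_o, f"{pair}_k_on")
        bind(f"{pair}_off_occ", off_o, f"{pair}_k_off", f"{pair}_m2")
    for name in ("k3", "k3_rev", "k4", "k4_rev", "k5", "k5_rev", "k6", "k6_rev",
                 "k7", "k7_rev", "k8", "k8_rev", "alpha_a", "alpha_b", "beta_p",
                 "beta_d", "K_a", "K_b", "delta"):
        bind(name, getattr(p, name), name)
    bind("alpha_d", p.alpha_d)  # dose input, not fitted
    bind("K_a_import", p.K_a * p.vbar, "K_a")
    bind("K_b_import", p.K_b * p.vbar, "K_b")

    species: list[Species] = []

    def add(sp: Species) -> Species:
        species.append(sp)
        return sp

    # free genetic states; the excised loop carries the blank sequence but no
    # promoter strand, every chromosomal state carries the promoter strand
    strand = {"S1": (True, True), "tS1": (True, True), "tS2": (True, True),
              "S2": (True, False), "SX": (False, True)}
    free = {tag: add(Species(None, tag, "free", *strand[tag]))
            for tag in FREE_DNA_TAGS}
    for tag in PROTEIN_TAGS:
        add(Species(None, tag, "free", False, False))

    reactions: list[Reaction] = []

    def rxn(name, reactants, products, ref):
        reactions.append(Reaction(name, tuple(reactants), tuple(products), ref))

    for path, sub, prods, pair, is_exc in _EVENTS:
        # strand bookkeeping inside the event: complexes inherit the DNA content
        # of the species they are built on; HJ complexes contain the intact
        # substrate DNA (promoter strand + blank unit where the substrate has them)
        sub_strand = strand[sub]

        def C(tag, occ, strands):
            return add(Species(path, tag, occ, *strands))

        cplx = {("sub", occ): C(sub, occ, sub_strand)
                for occ in ("F1", "F1_1", "F2_0", "F3", "F4")}
        hj = {tag: C(tag, "F4", sub_strand) for tag in HJ_TAGS}

        # substrate binding cascade
        for frm, to, on_kind, off_kind in _CASCADE:
            frm_name = free[sub].name if frm == "free" else cplx[("sub", frm)].name
            to_name = cplx[("sub", to)].name
            rxn(f"{path}:{frm}+F->{to}", [(frm_name, 1), ("F", 1)], [(to_name, 1)],
                f"{pair}_on_{ 'free' if on_kind == 'on_free' else 'occ'}")
            rxn(f"{path}:{to}->{frm}+F", [(to_name, 1)], [(frm_name, 1), ("F", 1)],
                f"{pair}_off_{'free' if off_kind == 'off_free' else 'occ'}")

        # junction entry from the substrate side and the internal ladder
        rxn(f"{path}:F4->HJ1", [(cplx[('sub', 'F4')].name, 1)], [(hj['HJ1'].name, 1)], "k3")
        rxn(f"{path}:HJ1->F4", [(hj['HJ1'].name, 1)], [(cplx[('sub', 'F4')].name, 1)], "k3_rev")
        for i, kref in zip(range(1, 5), ("k4", "k5", "k6", "k7")):
            a, b = hj[f"HJ{i}"].name, hj[f"HJ{i + 1}"].name
            rxn(f"{path}:HJ{i}->HJ{i + 1}", [(a, 1)], [(b, 1)], kref)
            rxn(f"{path}:HJ{i + 1}->HJ{i}", [(b, 1)], [(a, 1)], f"{kref}_rev")

        if not is_exc:
            # mirrored product-side cascade: HJ5 <-> product.F4 <-> ... <-> free product
            prod = prods[0]
            pc = {occ: C(prod, occ, strand[prod])
                  for occ in ("F4", "F3", "F1_1", "F2_0", "F1")}
            rxn(f"{path}:HJ5->{prod}.F4", [(hj['HJ5'].name, 1)], [(pc['F4'].name, 1)], "k3_rev")
            rxn(f"{path}:{prod}.F4->HJ5", [(pc['F4'].name, 1)], [(hj['HJ5'].name, 1)], "k3")
            mirror = (
                ("F4", "F3", "off_occ", "on_occ"),
                ("F3", "F1_1", "off_occ", "on_occ"),
                ("F3", "F2_0", "off_free", "on_free"),
                ("F1_1", "F1", "off_free", "on_free"),
                ("F2_0", "F1", "off_occ", "on_occ"),
            )
            for frm, to, off_kind, on_kind in mirror:
                rxn(f"{path}:{prod}.{frm}->{prod}.{to}+F",
                    [(pc[frm].name, 1)], [(pc[to].name, 1), ("F", 1)], f"{pair}_{off_kind}")
                rxn(f"{path}:{prod}.{to}+F->{prod}.{frm}",
                    [(pc[to].name, 1), ("F", 1)], [(pc[frm].name, 1)], f"{pair}_{on_kind}")
            rxn(f"{path}:{prod}.F1->{prod}+F",
                [(pc['F1'].name, 1)], [(free[prod].name, 1), ("F", 1)], f"{pair}_off_free")
            rxn(f"{path}:{prod}+F->{prod}.F1",
                [(free[prod].name, 1), ("F", 1)], [(pc['F1'].name, 1)], f"{pair}_on_free")
        else:
            # resolution into two disparate products, each on its own composite
            # site with two bound monomers, then independent dissociation
            pcs = {}
            for prod in prods:
                pcs[prod] = {occ: C(prod, occ, strand[prod]) for occ in ("F2", "F1")}
            s2c, sxc = pcs["S2"], pcs["SX"]
            rxn(f"{path}:HJ5->S2.F2+SX.F2", [(hj['HJ5'].name, 1)],
                [(s2c['F2'].name, 1), (sxc['F2'].name, 1)], "k8")
            rxn(f"{path}:S2.F2+SX.F2->HJ5",
                [(s2c['F2'].name, 1), (sxc['F2'].name, 1)], [(hj['HJ5'].name, 1)], "k8_rev")
            for prod in prods:
                pc = pcs[prod]
                rxn(f"{path}:{prod}.F2->{prod}.F1+F",
                    [(pc['F2'].name, 1)], [(pc['F1'].name, 1), ("F", 1)], f"{pair}_off_occ")
                rxn(f"{path}:{prod}.F1+F->{prod}.F2",
                    [(pc['F1'].name, 1), ("F", 1)], [(pc['F2'].name, 1)], f"{pair}_on_occ")
                rxn(f"{path}:{prod}.F1->{prod}+F",
                    [(pc['F1'].name, 1)], [(free[prod].name, 1), ("F", 1)], f"{pair}_off_free")
                rxn(f"{path}:{prod}+F->{prod}.F1",
                    [(free[prod].name, 1), ("F", 1)], [(pc['F1'].name, 1)], f"{pair}_on_free")

    # FlpO expression / activation / degradation and the inducer channel.
    # Nuclear import is volume-corrected on the production side only: the
    # cytosolic pools deplete at K*[..] while nuclear F accrues at K*vbar*[..],
    # realised as a consumption reaction plus a catalytic production reaction.
    rxn("expr:->Fa", [], [("Fa", 1)], "alpha_a")
    rxn("expr:->Fb", [], [("Fb", 1)], "alpha_b")
    rxn("dose:->OHT", [], [("OHT", 1)], "alpha_d")
    rxn("deg:F->", [("F", 1)], [], "beta_p")
    rxn("deg:Fa->", [("Fa", 1)], [], "beta_p")
    rxn("deg:Fb->", [("Fb", 1)], [], "beta_p")
    rxn("deg:OHT->", [("OHT", 1)], [], "beta_d")
    rxn("act:Fa+OHT->", [("Fa", 1), ("OHT", 1)], [], "K_a")
    rxn("act:Fa+OHT->Fa+OHT+F", [("Fa", 1), ("OHT", 1)],
        [("Fa", 1), ("OHT", 1), ("F", 1)], "K_a_import")
    rxn("leak:Fb->", [("Fb", 1)], [], "K_b")
    rxn("leak:Fb->Fb+F", [("Fb", 1)], [("Fb", 1), ("F", 1)], "K_b_import")
    rxn("dilution:SX->", [("SX", 1)], [], "delta")

    return ReactionNetwork(species, reactions, rate_values, deps, params)


def mass_action_rhs(network: ReactionNetwork, state) -> np.ndarray:
    """Mass-action derivative: stoichiometry matrix times the flux vector."""
    state = np.asarray(state, dtype=float)
    if state.shape != (network.n_species,):
        raise ValueError(
            f"state has length {state.shape}, expected ({network.n_species},)")
    return network.stoichiometry_matrix @ network.flux_vector(state)


def mechanistic_initial_state(network: ReactionNetwork, dose_au: float = 0.0,
                              total_dna: float = 1.0) -> np.ndarray:
    """All DNA in free State 1; inducer at ``dose_au``; no FlpO anywhere."""
    if dose_au < 0 or total_dna <= 0:
        raise ValueError("dose_au must be >= 0 and total_dna > 0")
    y = np.zeros(network.n_species)
    y[network.index["S1"]] = total_dna
    y[network.index["OHT"]] = dose_au
    return y


def state_totals(network: ReactionNetwork, state,
                 weights: dict[str, float] | None = None) -> tuple[float, float]:
    """Aggregate a state vector into (State-1 group, CAR-expressing group).

    The State-1 group holds the free S1 DNA, the substrate-side binding
    cascades of both inversions and the inversion Holliday-junction ladders
    (the group boundary is the HJ5 <-> product.F4 transition).  Everything
    else genetic is CAR-expressing; each excision-product species (the
    shortened S2 strand and the excised SX loop) counts with weight 1/2 so
    one excised parental DNA contributes one unit, preserving mass in the
    aggregate report.  ``weights`` may override the weight of any species by
    name.
    """
    state = np.asarray(state, dtype=float)
    if state.shape != (network.n_species,):
        raise ValueError("state length does not match the network")
    s1_total = 0.0
    expressing = 0.0
    for i, sp in enumerate(network.species):
        if not sp.is_dna:
            continue
        in_s1 = (sp.state_tag == "S1") or (
            sp.pathway in ("i1", "i2") and sp.state_tag in HJ_TAGS)
        if weights is not None and sp.name in weights:
            w = weights[sp.name]
        elif in_s1:
            w = 1.0
        elif sp.state_tag in ("S2", "SX"):
            w = 0.5
        else:
            w = 1.0
        if in_s1:
            s1_total += w * state[i]
        else:
            expressing += w * state[i]
    return s1_total, expressing
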