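"""Reaction channels of the type 1 / type 2 caspase network.

Kinetic rate constants are mapped onto per-attempt acceptance probabilities:

* ``P_on  = 1e2  * k_on``   (k_on in nM^-1 s^-1)
* ``P_off = 1e-4 * k_off``  (k_off in s^-1; 1e-4 s is half an MC time step)
* ``P_cat = 1e-4 * k_cat``

Bimolecular channels fire only between site-adjacent reactants; the complex
forms at the sampled molecule's site and the partner site is freed.
Catalysis is explicit: substrate binding, then a catalytic conversion of the
complex that releases enzyme and product (the product is placed on a random
free neighbor site).

The published description fixes two binding anchors (caspase 8-Bid association
constant k_A ~ 1 nM^-1, caspase 8-procaspase 3 k_A ~ 1.67e-4 nM^-1) and the
qualitative regimes of the remaining channels (low-probability cytochrome
c-Apaf binding, rapid post-apoptosome caspase processing, a weak direct
Bid-Bax activation route).  The numeric defaults below realise those
constraints and are all overridable per channel in the configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import lattice as L

P_ON_FACTOR = 1e2      # nM s
P_OFFCAT_FACTOR = 1e-4  # s (half an MC time step)


@dataclass(frozen=True)
class RateTriple:
    """Kinetic rates of one channel: association, dissociation, catalysis."""

    k_on: float = 0.0    # nM^-1 s^-1
    k_off: float = 0.0   # s^-1
    k_cat: float = 0.0   # s^-1

    def __post_init__(self) -> None:
        if min(self.k_on, self.k_off, self.k_cat) < 0:
            raise ValueError("rate constants must be >= 0")

    @property
    def k_A(self) -> float:
        """Association constant k_on/k_off in nM^-1."""
        if self.k_off == 0:
            raise ZeroDivisionError("k_off is zero; k_A undefined")
        return self.k_on / self.k_off


@dataclass(frozen=True)
class ProbabilityTriple:
    p_on: float
    p_off: float
    p_cat: float


def map_kinetic_rates(rates: RateTriple) -> ProbabilityTriple:
    """Exact algebraic mapping of kinetic rates to per-attempt probabilities."""
    p = ProbabilityTriple(p_on=P_ON_FACTOR * rates.k_on,
                          p_off=P_OFFCAT_FACTOR * rates.k_off,
                          p_cat=P_OFFCAT_FACTOR * rates.k_cat)
    for name, v in (("P_on", p.p_on), ("P_off", p.p_off), ("P_cat", p.p_cat)):
        if v > 1.0:
            raise ValueError(
                f"{name} = {v:g} > 1: rate too fast for the MC time step")
    return p


#: Channel catalog with reconstructed default rates (see module docstring).
DEFAULT_RATES: dict[str, RateTriple] = {
    # type 1: caspase 8 processes procaspase 3 (weak affinity, slow turnover)
    "c8_proc3": RateTriple(k_on=1e-4, k_off=0.6, k_cat=0.1),
    # caspase 8 cleaves Bid to tBid (k_A = 1 nM^-1; efficient turnover)
    "c8_bid": RateTriple(k_on=1e-4, k_off=1e-4, k_cat=10.0),
    # tBid recruits Bax on the mitochondrial membrane
    "tbid_bax": RateTriple(k_on=1e-4, k_off=1e-3),
    # second Bax joins tBid:Bax and the pair detaches as an active dimer
    "bax_dimer": RateTriple(k_on=1e-4),
    # direct (low-probability) Bid activation of Bax
    "bid_bax": RateTriple(k_on=1e-7, k_off=1e-3),
    "bid_bax_dimer": RateTriple(k_on=1e-4),
    # Bcl2 sequesters tBid and Bax
    "bcl2_tbid": RateTriple(k_on=1e-4, k_off=1e-4),
    "bcl2_bax": RateTriple(k_on=1e-4, k_off=1e-4),
    # low-probability cytochrome c-Apaf association (rate-limiting, Table-2 knob)
    "cytc_apaf": RateTriple(k_on=1e-6, k_off=1e-4),
    # two cytc:Apaf halves join into the apoptosome
    "apoptosome": RateTriple(k_on=1e-4),
    # apoptosome processes procaspase 9 (rapid once formed)
    "apo_proc9": RateTriple(k_on=1e-4, k_off=1e-3, k_cat=10.0),
    # caspase 9 processes procaspase 3 (rapid)
    "c9_proc3": RateTriple(k_on=1e-4, k_off=1e-3, k_cat=10.0),
    # XIAP sequestration of procaspase 9 / caspase 9 / caspase 3; reversible
    # on simulation timescales so XIAP redistributes among its targets
    "xiap_proc9": RateTriple(k_on=1e-4, k_off=1e-2),
    "xiap_c9": RateTriple(k_on=1e-4, k_off=1e-2),
    "xiap_c3": RateTriple(k_on=1e-4, k_off=1e-2),
    # Smac antagonism of XIAP (sequesters free XIAP only)
    "smac_xiap": RateTriple(k_on=1e-4, k_off=1e-4),
}

CHANNELS = tuple(DEFAULT_RATES)

#: Provenance codes for caspase-3 producing channels.
PROV_NONE, PROV_VIA_C8, PROV_VIA_C9 = 0, 1, 2

#: Human-readable provenance tags (fixed strings, also used by the CLI).
PROVENANCE_TAGS = {
    PROV_VIA_C8: "caspase3 activated by caspase8",
    PROV_VIA_C9: "caspase3 activated by caspase9",
}


@dataclass(frozen=True)
class ReactionRule:
    """One reaction channel in a form suitable for inspection and testing."""

    name: str
    kind: str                      # bind | unbind | catalyze | convert | exchange
    reactants: tuple[int, ...]
    products: tuple[int, ...]
    probability: float
    provenance: int = PROV_NONE

    def mass_balanced(self) -> bool:
        lhs = sum(L.CONSTITUENTS[s] for s in self.reactants)
        rhs = sum(L.CONSTITUENTS[s] for s in self.products)
        return bool(np.array_equal(lhs, rhs))


@dataclass(frozen=True)
class ReleaseRule:
    """All-or-none mitochondrial release of cytochrome c and Smac.

    Fires at most once, when the active Bax-dimer count reaches ``threshold``;
    every cytochrome c and Smac molecule is then retagged cytosolic.
    """

    threshold: int = 10
    trigger_species: int = L.BAX2
    released_species: tuple[int, ...] = (L.CYTC, L.SMAC)

    def __post_init__(self) -> None:
        if self.threshold < 1:
            raise ValueError("release threshold must be >= 1")


# --------------------------------------------------------------------------
# rule-table compilation
# --------------------------------------------------------------------------

# unimolecular rule kinds
K_UNBIND, K_CATALYZE, K_CONVERT = 1, 2, 3
# bimolecular rule kinds
K_BIND, K_EXCHANGE = 0, 4


@dataclass
class RuleTables:
    """Integer/float tables driving the Monte Carlo kernels.

    ``pair_rule[a, b]`` gives the bimolecular rule triggered when a sampled
    molecule of species ``a`` reacts with an adjacent ``b`` (-1 if none).
    ``uni_start/uni_count`` index the per-species unimolecular rules.
    """

    pair_rule: np.ndarray
    bi_prob: np.ndarray
    bi_kind: np.ndarray
    bi_prod_a: np.ndarray
    bi_prod_b: np.ndarray
    bi_complex_side: np.ndarray

    uni_start: np.ndarray
    uni_count: np.ndarray
    uni_kind: np.ndarray
    uni_prob: np.ndarray
    uni_prod_site: np.ndarray
    uni_prod_nbr: np.ndarray
    uni_nbr_comp: np.ndarray      # 0 = cytosolic, 9 = inherit complex compartment
    uni_prov: np.ndarray
    uni_needs_shell: np.ndarray   # rule applies only on the mito shell

    rules: list = field(default_factory=list)   # ReactionRule descriptions


def default_rule_catalog(rates: dict[str, RateTriple] | None = None,
                         tbid_translocation_prob: float = 1.0) -> list[ReactionRule]:
    """The full channel list as inspectable :class:`ReactionRule` objects."""
    r = dict(DEFAULT_RATES)
    if rates:
        unknown = set(rates) - set(DEFAULT_RATES)
        if unknown:
            raise ValueError(f"unknown rate channel(s): {sorted(unknown)}")
        r.update(rates)
    P = {name: map_kinetic_rates(t) for name, t in r.items()}
    rules: list[ReactionRule] = []

    def bind(name, a, b, prod):
        rules.append(ReactionRule(name, "bind", (a, b), (prod,), P[name].p_on))

    def unbind(name, cx, keep, go):
        rules.append(ReactionRule(name + "_off", "unbind", (cx,), (keep, go),
                                  P[name].p_off))

    def cat(name, cx, enzyme, product, prov=PROV_NONE):
        rules.append(ReactionRule(name + "_cat", "catalyze", (cx,),
                                  (enzyme, product), P[name].p_cat, prov))

    bind("c8_proc3", L.C8, L.PROC3, L.C8_PROC3)
    unbind("c8_proc3", L.C8_PROC3, L.C8, L.PROC3)
    cat("c8_proc3", L.C8_PROC3, L.C8, L.C3, PROV_VIA_C8)

    bind("c8_bid", L.C8, L.BID, L.C8_BID)
    unbind("c8_bid", L.C8_BID, L.C8, L.BID)
    cat("c8_bid", L.C8_BID, L.C8, L.TBID)

    rules.append(ReactionRule("tbid_translocation", "convert", (L.TBID,),
                              (L.TBID,), tbid_translocation_prob))

    bind("tbid_bax", L.TBID, L.BAX, L.TBID_BAX)
    unbind("tbid_bax", L.TBID_BAX, L.TBID, L.BAX)
    rules.append(ReactionRule("bax_dimer", "exchange", (L.TBID_BAX, L.BAX),
                              (L.TBID, L.BAX2), P["bax_dimer"].p_on))

    bind("bid_bax", L.BID, L.BAX, L.BID_BAX)
    unbind("bid_bax", L.BID_BAX, L.BID, L.BAX)
    rules.append(ReactionRule("bid_bax_dimer", "exchange", (L.BID_BAX, L.BAX),
                              (L.BID, L.BAX2), P["bid_bax_dimer"].p_on))

    bind("bcl2_tbid", L.BCL2, L.TBID, L.BCL2_TBID)
    unbind("bcl2_tbid", L.BCL2_TBID, L.TBID, L.BCL2)
    bind("bcl2_bax", L.BCL2, L.BAX, L.BCL2_BAX)
    unbind("bcl2_bax", L.BCL2_BAX, L.BCL2, L.BAX)

    bind("cytc_apaf", L.CYTC, L.APAF, L.CYTC_APAF)
    unbind("cytc_apaf", L.CYTC_APAF, L.CYTC, L.APAF)
    bind("apoptosome", L.CYTC_APAF, L.CYTC_APAF, L.APO)

    bind("apo_proc9", L.APO, L.PROC9, L.APO_PROC9)
    unbind("apo_proc9", L.APO_PROC9, L.APO, L.PROC9)
    cat("apo_proc9", L.APO_PROC9, L.APO, L.C9)

    bind("c9_proc3", L.C9, L.PROC3, L.C9_PROC3)
    unbind("c9_proc3", L.C9_PROC3, L.C9, L.PROC3)
    cat("c9_proc3", L.C9_PROC3, L.C9, L.C3, PROV_VIA_C9)

    bind("xiap_proc9", L.XIAP, L.PROC9, L.XIAP_PROC9)
    unbind("xiap_proc9", L.XIAP_PROC9, L.XIAP, L.PROC9)
    bind("xiap_c9", L.XIAP, L.C9, L.XIAP_C9)
    unbind("xiap_c9", L.XIAP_C9, L.XIAP, L.C9)
    bind("xiap_c3", L.XIAP, L.C3, L.XIAP_C3)
    unbind("xiap_c3", L.XIAP_C3, L.XIAP, L.C3)
    bind("smac_xiap", L.SMAC, L.XIAP, L.SMAC_XIAP)
    unbind("smac_xiap", L.SMAC_XIAP, L.SMAC, L.XIAP)
    return rules


def compile_rule_tables(rates: dict[str, RateTriple] | None = None,
                        tbid_translocation_prob: float = 1.0) -> RuleTables:
    """Compile the catalog into flat numba-friendly arrays."""
    rules = default_rule_catalog(rates, tbid_translocation_prob)

    # --- bimolecular ------------------------------------------------------
    ns = L.N_SPECIES
    pair_rule = np.full((ns, ns), -1, dtype=np.int64)
    bi_prob: list[float] = []
    bi_kind: list[int] = []
    bi_prod_a: list[int] = []
    bi_prod_b: list[int] = []
    bi_cxside: list[int] = []

    def add_ordered(a, b, prob, kind, prod_a, prod_b, cxside):
        idx = len(bi_prob)
        if pair_rule[a, b] != -1:
            raise ValueError(f"duplicate bimolecular rule for pair ({a},{b})")
        pair_rule[a, b] = idx
        bi_prob.append(prob)
        bi_kind.append(kind)
        bi_prod_a.append(prod_a)
        bi_prod_b.append(prod_b)
        bi_cxside.append(cxside)

    for rule in rules:
        if rule.kind == "bind":
            a, b = rule.reactants
            (prod,) = rule.products
            add_ordered(a, b, rule.probability, K_BIND, prod, -1, -1)
            if a != b:
                add_ordered(b, a, rule.probability, K_BIND, prod, -1, -1)
        elif rule.kind == "exchange":
            cx, mono = rule.reactants
            freed, dimer = rule.products
            # the dimer (prod_a) forms at the complex's site; the freed
            # activator (prod_b) takes the monomer's site, back in the cytosol
            add_ordered(cx, mono, rule.probability, K_EXCHANGE, dimer, freed, 0)
            add_ordered(mono, cx, rule.probability, K_EXCHANGE, dimer, freed, 1)

    # --- unimolecular -----------------------------------------------------
    per_species: dict[int, list] = {}
    for rule in rules:
        if rule.kind in ("unbind", "catalyze", "convert"):
            per_species.setdefault(rule.reactants[0], []).append(rule)

    uni_start = np.zeros(ns, dtype=np.int64)
    uni_count = np.zeros(ns, dtype=np.int64)
    uni_kind: list[int] = []
    uni_prob: list[float] = []
    uni_prod_site: list[int] = []
    uni_prod_nbr: list[int] = []
    uni_nbr_comp: list[int] = []
    uni_prov: list[int] = []
    uni_needs_shell: list[int] = []

    for sp in range(ns):
        uni_start[sp] = len(uni_kind)
        for rule in per_species.get(sp, []):
            if rule.kind == "convert":
                uni_kind.append(K_CONVERT)
                uni_prod_site.append(rule.products[0])
                uni_prod_nbr.append(-1)
                uni_nbr_comp.append(0)
                uni_needs_shell.append(1)
            else:
                uni_kind.append(K_UNBIND if rule.kind == "unbind" else K_CATALYZE)
                keep, go = rule.products
                uni_prod_site.append(keep)
                uni_prod_nbr.append(go)
                # a tBid leaving a membrane-resident complex stays on the shell
                uni_nbr_comp.append(9 if go == L.TBID else 0)
                uni_needs_shell.append(0)
            uni_prob.append(rule.probability)
            uni_prov.append(rule.provenance)
        uni_count[sp] = len(uni_kind) - uni_start[sp]

    tables = RuleTables(
        pair_rule=pair_rule,
        bi_prob=np.array(bi_prob, dtype=np.float64),
        bi_kind=np.array(bi_kind, dtype=np.int64),
        bi_prod_a=np.array(bi_prod_a, dtype=np.int64),
        bi_prod_b=np.array(bi_prod_b, dtype=np.int64),
        bi_complex_side=np.array(bi_cxside, dtype=np.int64),
        uni_start=uni_start, uni_count=uni_count,
        uni_kind=np.array(uni_kind, dtype=np.int64),
        uni_prob=np.array(uni_prob, dtype=np.float64),
        uni_prod_site=np.array(uni_prod_site, dtype=np.int64),
        uni_prod_nbr=np.array(uni_prod_nbr, dtype=np.int64),
        uni_nbr_comp=np.array(uni_nbr_comp, dtype=np.int64),
        uni_prov=np.array(uni_prov, dtype=np.int64),
        uni_needs_shell=np.array(uni_needs_shell, dtype=np.int64),
        rules=rules)
    return tables


# --------------------------------------------------------------------------
# single-attempt operations (Python surface over the kernels)
# --------------------------------------------------------------------------

def attempt_reaction(state, molecule: int, tables: RuleTables,
                     seed: int | None = None) -> int:
    """Attempt one reaction move for a live molecule.

    One applicable rule (unimolecular for the species, or bimolecular with an
    adjacent partner) is selected uniformly at random and fires if a uniform
    draw falls below its probability.  Returns the provenance code of a
    caspase-3 producing event (0 otherwise, including rejections).
    """
    from . import _kernels as K
    if state.act_idx[molecule] < 0:
        raise ValueError(f"molecule {molecule} is not alive")
    if seed is not None:
        K.seed_rng(seed)
    return int(K.react_one(
        state.occ, state.msite, state.species, state.comp,
        state.act, state.act_idx, state.counts,
        state.nbr, state.in_block, state.is_shell, state.regs, molecule,
        tables.pair_rule, tables.bi_prob, tables.bi_kind,
        tables.bi_prod_a, tables.bi_prod_b, tables.bi_complex_side,
        tables.uni_start, tables.uni_count, tables.uni_kind, tables.uni_prob,
        tables.uni_prod_site, tables.uni_prod_nbr, tables.uni_nbr_comp,
        tables.uni_prov, tables.uni_needs_shell, state.free_stack,
        np.zeros(32, dtype=np.int64)))


def check_release(state, rule: ReleaseRule) -> bool:
    """Fire the all-or-none release if the Bax-dimer threshold is reached.

    Idempotent: returns True only on the step at which release fires.
    """
    if state.released:
        return False
    if state.counts[rule.trigger_species] < rule.threshold:
        return False
    live = state.act[: state.n_molecules]
    inside = live[state.comp[live] == L.MITO_INTERIOR]
    state.comp[inside] = L.CYTOSOL
    state.regs[state.R_RELEASED] = 1
    state.regs[state.R_RELEASE_STEP] = state.regs[state.R_STEP]
    return True
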