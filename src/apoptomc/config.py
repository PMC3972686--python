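"""Configuration, presets, and serialization.

A :class:`SimConfig` fully parameterizes one in-silico cell: lattice geometry,
initial concentrations (nM; one molecule per nM at the reference 60^3
volume), kinetic rate triples per channel, the DISC block, release threshold,
and stop conditions.  Presets encode each published scenario by name, plus a
family of desk-scale fixtures (``desk_*``) that shrink the lattice and copy
numbers together so sweeps complete quickly while preserving the orderings
the full-scale model exhibits.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .kinetics import DEFAULT_RATES, RateTriple, map_kinetic_rates
from .lattice import LatticeSpec, SEEDABLE_SPECIES


@dataclass(frozen=True)
class DiscConfig:
    """Membrane DISC model parameters.

    ``p_on``/``p_off`` are the adaptor activity-switching probabilities per
    sampled attempt (death-ligand induction knob); ``e_dd`` is the
    active-active nearest-neighbor pair energy in units of k_B T (attractive
    when negative; -2 unless a scenario says otherwise); ``p_c8`` the
    per-attempt probability that an eligible active adaptor converts one
    procaspase 8 from the pool into active caspase 8; eligibility requires at
    least ``min_active_neighbors`` active nearest neighbors (cluster
    membership).
    """

    enabled: bool = False
    adaptor_density: float = 0.1
    n_adaptors: int | None = None
    p_on: float = 1.0
    p_off: float = 1e-3
    e_dd: float = -2.0
    p_c8: float = 1e-4
    min_active_neighbors: int = 1
    proc8_pool: int = 20

    def __post_init__(self) -> None:
        for name in ("p_on", "p_off", "p_c8"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 <= self.adaptor_density <= 1.0:
            raise ValueError("adaptor_density must be in [0, 1]")
        if self.min_active_neighbors < 0 or self.proc8_pool < 0:
            raise ValueError("min_active_neighbors and proc8_pool must be >= 0")

    def resolved_adaptor_count(self, lattice: LatticeSpec) -> int:
        if self.n_adaptors is not None:
            return self.n_adaptors
        return int(round(self.adaptor_density * lattice.nx * lattice.ny))


@dataclass(frozen=True)
class StopConfig:
    """Run termination: half-maximal free caspase 3 (a count) or a step cap."""

    half_max_count: int = 50
    max_steps: int = 10**8
    stop_on_first_apoptosome: bool = False

    def __post_init__(self) -> None:
        if self.half_max_count < 1 or self.max_steps < 1:
            raise ValueError("half_max_count and max_steps must be >= 1")


@dataclass(frozen=True)
class SimConfig:
    """Full parameterization of one simulated cell."""

    lattice: LatticeSpec = field(default_factory=LatticeSpec)
    concentrations: dict = field(default_factory=dict)
    rates: dict = field(default_factory=dict)
    release_threshold: int = 10
    tbid_translocation_prob: float = 1.0
    p_diff_cytosol: float = 0.1
    p_diff_membrane: float = 0.01
    disc: DiscConfig = field(default_factory=DiscConfig)
    stop: StopConfig = field(default_factory=StopConfig)
    record_every: int = 10**4

    def __post_init__(self) -> None:
        unknown = set(self.concentrations) - set(SEEDABLE_SPECIES)
        if unknown:
            raise ValueError(f"unknown species in concentrations: {sorted(unknown)}")
        for name, c in self.concentrations.items():
            if c < 0:
                raise ValueError(f"negative concentration for {name}: {c}")
        unknown = set(self.rates) - set(DEFAULT_RATES)
        if unknown:
            raise ValueError(f"unknown rate channel(s): {sorted(unknown)}")
        for name, t in self.rates.items():
            map_kinetic_rates(t)   # raises if any mapped probability > 1
        for name in ("p_diff_cytosol", "p_diff_membrane",
                     "tbid_translocation_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.release_threshold < 1:
            raise ValueError("release_threshold must be >= 1")
        if self.record_every < 1:
            raise ValueError("record_every must be >= 1")

    def full_rates(self) -> dict:
        r = dict(DEFAULT_RATES)
        r.update(self.rates)
        return r

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)


# --------------------------------------------------------------------------
# serialization
# --------------------------------------------------------------------------

def config_to_dict(cfg: SimConfig) -> dict:
    d = asdict(cfg)
    d["lattice"]["mito_dims"] = list(cfg.lattice.mito_dims)
    d["rates"] = {k: [t.k_on, t.k_off, t.k_cat] for k, t in cfg.rates.items()}
    return d


def config_from_dict(d: dict) -> SimConfig:
    d = dict(d)
    known = {f.name for f in dataclasses.fields(SimConfig)}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown configuration key(s): {sorted(unknown)}")
    if "lattice" in d:
        lat = dict(d["lattice"])
        bad = set(lat) - {f.name for f in dataclasses.fields(LatticeSpec)}
        if bad:
            raise ValueError(f"unknown lattice key(s): {sorted(bad)}")
        if "mito_dims" in lat:
            lat["mito_dims"] = tuple(lat["mito_dims"])
        d["lattice"] = LatticeSpec(**lat)
    if "rates" in d:
        d["rates"] = {k: RateTriple(*v) if not isinstance(v, RateTriple) else v
                      for k, v in d["rates"].items()}
    if "disc" in d and not isinstance(d["disc"], DiscConfig):
        d["disc"] = DiscConfig(**d["disc"])
    if "stop" in d and not isinstance(d["stop"], StopConfig):
        d["stop"] = StopConfig(**d["stop"])
    return SimConfig(**d)


def save_config(cfg: SimConfig, path: str | Path) -> None:
    path = Path(path)
    d = config_to_dict(cfg)
    if path.suffix == ".json":
        path.write_text(json.dumps(d, indent=2))
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=False))


def load_config(path: str | Path) -> SimConfig:
    """Load and fully validate a YAML (or JSON) configuration file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(d, dict):
        raise ValueError(f"{path} does not contain a configuration mapping")
    return config_from_dict(d)


def scale_config(cfg: SimConfig, factor: float) -> SimConfig:
    """Shrink lattice and copy numbers together (volume-proportional).

    Linear dimensions are multiplied by ``factor`` and every copy number,
    the half-max stop count and the release threshold by ``factor**3``, so
    nM-equivalents are preserved.  Probabilities are untouched.
    """
    if not 0 < factor <= 1:
        raise ValueError("scale factor must be in (0, 1]")
    if factor == 1.0:
        return cfg
    vol = factor**3
    lat = cfg.lattice
    dims = tuple(max(2, round(n * factor)) for n in (lat.nx, lat.ny, lat.nz))
    mito = tuple(round(m * factor) for m in lat.mito_dims)
    new_lat = LatticeSpec(nx=dims[0], ny=dims[1], nz=dims[2],
                          dx_nm=lat.dx_nm, dt_s=lat.dt_s, mito_dims=mito)
    conc = {k: v * vol for k, v in cfg.concentrations.items()}
    stop = dataclasses.replace(
        cfg.stop, half_max_count=max(1, round(cfg.stop.half_max_count * vol)))
    return cfg.replace(lattice=new_lat, concentrations=conc, stop=stop,
                       release_threshold=max(1, round(cfg.release_threshold * vol)))


# --------------------------------------------------------------------------
# presets
# --------------------------------------------------------------------------

#: Baseline concentrations (nM).  Caspase 8, XIAP, Smac, Apaf and procaspase 3
#: are stated in the scenarios; the rest are documented reconstructions.
BASELINE_NM = {
    "C8": 1.0, "proC3": 100.0, "Bid": 50.0, "Bax": 80.0, "Bcl2": 20.0,
    "cytc": 100.0, "Smac": 50.0, "Apaf": 100.0, "proC9": 20.0, "XIAP": 30.0,
}


def _full(over: dict | None = None, **kw) -> SimConfig:
    conc = dict(BASELINE_NM)
    if over:
        conc.update(over)
    return SimConfig(concentrations=conc, **kw)


_CANCER_DISC = DiscConfig(enabled=True, p_on=1.0, p_off=1e-3, e_dd=-2.0,
                          proc8_pool=20)

# desk-scale fixture geometry: 8^3 lattice, 3^3 centered mitochondrion
_DESK_LAT = LatticeSpec(nx=8, ny=8, nz=8, mito_dims=(3, 3, 3))
DESK_NM = {
    "C8": 1.0, "proC3": 12.0, "Bid": 6.0, "Bax": 10.0, "Bcl2": 2.0,
    "cytc": 6.0, "Smac": 3.0, "Apaf": 12.0, "proC9": 5.0, "XIAP": 3.0,
}
_DESK_STOP = StopConfig(half_max_count=6, max_steps=200_000)


#: Desk fixtures scale slow residence times along with the run length:
#: XIAP-complex lifetimes are shortened by the same factor as the number of
#: MC steps, so XIAP redistributes among its targets within a desk run just
#: as it does over a full-length run.
DESK_RATES = {
    "xiap_proc9": RateTriple(k_on=1e-4, k_off=0.3),
    "xiap_c9": RateTriple(k_on=1e-4, k_off=0.3),
    "xiap_c3": RateTriple(k_on=1e-4, k_off=0.3),
}


def _desk(over: dict | None = None, *, stop: StopConfig = _DESK_STOP,
          **kw) -> SimConfig:
    conc = dict(DESK_NM)
    if over:
        conc.update(over)
    kw.setdefault("release_threshold", 2)
    kw.setdefault("record_every", 1000)
    rates = dict(DESK_RATES)
    rates.update(kw.pop("rates", {}))
    return SimConfig(lattice=_DESK_LAT, concentrations=conc, stop=stop,
                     rates=rates, **kw)


def _build_presets() -> dict:
    p: dict[str, SimConfig] = {}

    # --- caspase 8 titration -------------------------------------------
    for name, c8 in (("fig2a", 1.0), ("fig2b", 5.0), ("fig2c", 10.0)):
        p[name] = _full({"C8": c8})

    # --- XIAP / Smac ratios (caspase 8 = 1 nM) -------------------------
    p["table1_ratio06"] = _full({"XIAP": 30.0, "Smac": 50.0})
    p["table1_ratio3"] = _full({"XIAP": 30.0, "Smac": 10.0})
    p["table1_ratio18"] = _full({"XIAP": 90.0, "Smac": 50.0})

    # --- cytochrome c-Apaf association scan ----------------------------
    base_kon = DEFAULT_RATES["cytc_apaf"]
    for name, f in (("table2_konx2", 2.0), ("table2_normal", 1.0),
                    ("table2_konx05", 0.5)):
        p[name] = _full(
            {}, rates={"cytc_apaf": RateTriple(k_on=base_kon.k_on * f,
                                               k_off=base_kon.k_off)},
            stop=StopConfig(half_max_count=50, max_steps=10**8,
                            stop_on_first_apoptosome=True))

    # --- Bid-deficient / XIAP-inhibited cells --------------------------
    for name, xiap in (("fig4a", 60.0), ("fig4b", 30.0), ("fig4c", 0.0)):
        p[name] = _full({"Bid": 0.0, "XIAP": xiap})
    for name, c8 in (("fig5a", 1.0), ("fig5b", 2.0), ("fig5c", 3.0)):
        p[name] = _full({"C8": c8, "XIAP": 0.0})

    # --- reduced Apaf --------------------------------------------------
    p["fig7_apaf20"] = _full({"Apaf": 20.0})

    # --- cancer overexpression panels ----------------------------------
    cancer = {"Bid": 100.0, "Bax": 160.0}
    for fig, bcl2 in (("fig11", 300.0), ("fig12", 1000.0)):
        for panel, (c8, xiap) in zip("abcdef", [(1, 30), (1, 90), (1, 150),
                                                (10, 30), (10, 90), (10, 150)]):
            p[f"{fig}{panel}"] = _full(
                {**cancer, "Bcl2": bcl2, "C8": float(c8), "XIAP": float(xiap)})

    # --- DISC clustering energy scan (death-ligand induced cancer cell) -
    for name, edd in (("fig15_edd0", 0.0), ("fig15_edd1", -1.0),
                      ("fig15_edd2", -2.0)):
        p[name] = _full(
            {**cancer, "Bcl2": 300.0, "XIAP": 90.0, "C8": 0.0},
            disc=dataclasses.replace(_CANCER_DISC, e_dd=edd))

    # --- intervention strategies on a resistant cancer cell ------------
    resistant = {**cancer, "Bcl2": 1000.0, "XIAP": 150.0, "C8": 0.0}
    p["fig16_i"] = _full({**resistant, "Bcl2": 300.0}, disc=_CANCER_DISC)
    p["fig16_ii"] = _full({**resistant, "Bcl2": 100.0}, disc=_CANCER_DISC)
    p["fig16_iii"] = _full({**resistant, "Bcl2": 300.0, "XIAP": 90.0},
                           disc=_CANCER_DISC)
    p["fig16_iv"] = _full({**resistant, "XIAP": 30.0}, disc=_CANCER_DISC)

    # --- ligand-sensitivity scenarios (normal vs cancer receptor levels)
    p["pon_1e-4"] = _full({"C8": 0.0},
                          disc=dataclasses.replace(_CANCER_DISC, p_on=1e-4,
                                                   p_off=1.0,
                                                   min_active_neighbors=0))
    p["pon_1e-5"] = _full({"C8": 0.0},
                          disc=dataclasses.replace(_CANCER_DISC, p_on=1e-5,
                                                   p_off=1.0,
                                                   min_active_neighbors=0))

    # --- desk-scale fixtures --------------------------------------------
    p["desk_baseline"] = _desk()
    p["desk_c8_low"] = _desk({"C8": 1.0})
    p["desk_c8_mid"] = _desk({"C8": 5.0})
    p["desk_c8_high"] = _desk({"C8": 10.0})

    p["desk_xiap_ratio06"] = _desk({"XIAP": 6.0, "Smac": 10.0})
    p["desk_xiap_ratio3"] = _desk({"XIAP": 6.0, "Smac": 2.0})
    p["desk_xiap_ratio18"] = _desk({"XIAP": 18.0, "Smac": 10.0})

    apo_stop = StopConfig(half_max_count=6, max_steps=150_000,
                          stop_on_first_apoptosome=True)
    for name, f in (("desk_apaf_fast", 2.0), ("desk_apaf_normal", 1.0),
                    ("desk_apaf_slow", 0.5)):
        p[name] = _desk(
            stop=apo_stop,
            rates={"cytc_apaf": RateTriple(k_on=base_kon.k_on * f,
                                           k_off=base_kon.k_off)})

    # DISC-only clustering scan: no cytosolic network, pool of 8
    disc_lat = LatticeSpec(nx=8, ny=8, nz=8, mito_dims=(0, 0, 0))
    for name, edd in (("desk_disc_edd0", 0.0), ("desk_disc_edd1", -1.0),
                      ("desk_disc_edd2", -2.0)):
        p[name] = SimConfig(
            lattice=disc_lat, concentrations={},
            disc=DiscConfig(enabled=True, n_adaptors=8, p_on=1.0,
                            p_off=1e-3, e_dd=edd, p_c8=1e-4, proc8_pool=8),
            stop=StopConfig(half_max_count=6, max_steps=12_000),
            record_every=500)

    # death-ligand dose analogs (receptor-activation strength ordering)
    lig_stop = StopConfig(half_max_count=6, max_steps=100_000)
    for name, (pon, poff) in (("desk_ligand_low", (5e-5, 0.1)),
                              ("desk_ligand_mid", (6e-4, 0.1)),
                              ("desk_ligand_high", (1.0, 1e-3))):
        p[name] = _desk(
            {"C8": 0.0}, stop=lig_stop,
            disc=DiscConfig(enabled=True, n_adaptors=10, p_on=pon,
                            p_off=poff, e_dd=-2.0, p_c8=1e-3,
                            min_active_neighbors=0, proc8_pool=8))
    return p


PRESETS = _build_presets()


def get_preset(name: str) -> SimConfig:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset '{name}'; available: {', '.join(sorted(PRESETS))}")
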