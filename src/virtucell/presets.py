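"""Canned scenario configurations S1-S8.

Each preset reproduces one of the published example conditions on the
default 10 × 10 × 10 µm cell:

S1/S2  free cytoplasmic molecules (2 nM, D = 5 µm² s⁻¹), epi / TIRF
S3/S4  free membrane molecules (1 µm⁻², D = 0.3 µm² s⁻¹), epi / TIRF
S5     membrane molecules among impermeable 1 × 1 µm² barrier fences, TIRF
S6     membrane molecules with 1 × 1 µm² lipid rafts (1 µm gaps,
       in-raft mobility ×0.1), TIRF
S7     cytoplasmic molecules (2 nM, D = 5) binding membrane targets
       (1 µm⁻², D = 0.001, dark), R_bind = 1e6 s⁻¹, R_diss = 0.05 s⁻¹,
       gated TIRF at 10 fps
S8     mobile membrane molecules (0.5 µm⁻², D = 0.3) binding immobile dark
       anchors (0.5 µm⁻²), R_bind = 1e5 s⁻¹, R_diss = 1 s⁻¹, TIRF
"""

from __future__ import annotations

import dataclasses

from .config import (BindingRule, IlluminationSpec, MembraneFeatureMap,
                     MoleculeClassSpec, SimulationConfig)

PRESET_NAMES = ("S1", "S2", "S3", "S4", "S5", "S6", "S7", "S8")


def _cytoplasm(**kw) -> MoleculeClassSpec:
    return MoleculeClassSpec(name="cytoplasmic", compartment="cytoplasm",
                             d_um2_s=5.0, concentration_nM=2.0, **kw)


def _membrane(**kw) -> MoleculeClassSpec:
    base = dict(name="membrane", compartment="membrane", d_um2_s=0.3,
                density_per_um2=1.0)
    base.update(kw)
    return MoleculeClassSpec(**base)


def scenario_preset(name: str, **overrides) -> SimulationConfig:
    """Configuration for one of the example scenarios S1..S8.

    Keyword overrides are applied to the top-level
    :class:`~virtucell.config.SimulationConfig` fields (e.g. ``seed=7``,
    ``duration_s=20``).
    """
    name = name.upper()
    if name not in PRESET_NAMES:
        raise KeyError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")

    if name == "S1":
        cfg = SimulationConfig(classes=[_cytoplasm()],
                               illumination=IlluminationSpec(mode="epi"))
    elif name == "S2":
        cfg = SimulationConfig(classes=[_cytoplasm()],
                               illumination=IlluminationSpec(mode="tirf"))
    elif name == "S3":
        cfg = SimulationConfig(classes=[_membrane()],
                               illumination=IlluminationSpec(mode="epi"))
    elif name == "S4":
        cfg = SimulationConfig(classes=[_membrane()],
                               illumination=IlluminationSpec(mode="tirf"))
    elif name == "S5":
        cfg = SimulationConfig(
            classes=[_membrane()],
            illumination=IlluminationSpec(mode="tirf"),
            membrane_features=MembraneFeatureMap(barrier_pitch_um=1.0,
                                                 barrier_permeability=0.0))
    elif name == "S6":
        cfg = SimulationConfig(
            classes=[_membrane()],
            illumination=IlluminationSpec(mode="tirf"),
            membrane_features=MembraneFeatureMap(raft_size_um=1.0,
                                                 raft_gap_um=1.0,
                                                 raft_mobility_ratio=0.1))
    elif name == "S7":
        cfg = SimulationConfig(
            classes=[
                _cytoplasm(bindings=[BindingRule(partner="targets",
                                                 r_bind=1e6, r_diss=0.05)]),
                MoleculeClassSpec(name="targets", compartment="membrane",
                                  d_um2_s=0.001, density_per_um2=1.0,
                                  n_tags=0),
            ],
            fps=10.0,
            illumination=IlluminationSpec(mode="tirf"))
    else:  # S8
        cfg = SimulationConfig(
            classes=[
                _membrane(density_per_um2=0.5,
                          bindings=[BindingRule(partner="anchors",
                                                r_bind=1e5, r_diss=1.0)]),
                MoleculeClassSpec(name="anchors", compartment="membrane",
                                  d_um2_s=0.0, density_per_um2=0.5,
                                  n_tags=0),
            ],
            illumination=IlluminationSpec(mode="tirf"))

    if overrides:
        cfg = dataclasses.replace(cfg, **overrides)
    return cfg
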