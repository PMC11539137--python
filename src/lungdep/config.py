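"""Reproducible experiment runs: configuration, manifests, presets.

A :class:`RunConfig` collects everything needed to regenerate a result
bit-for-bit: network source (generator parameters or a file), breathing
waveform, particle, discretization, constriction descriptor and seeds.
Defaults are the standard study conditions (Tb = 5 s, VT = 625 ml,
FRC = 3.3 l, total elastance 6.82 cmH2O/l, 4 um particles, dt = 0.01 s).
Configs load from YAML; every run writes a manifest with the config hash
and package version.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from typing import Optional

import numpy as np

from . import constriction as con
from .fixtures import make_fixture
from .generate import GeneratorParams, generate_tree
from .network import AirwayNetwork, read_network
from .particles import GasProperties, ParticleProperties
from .transport import run_breath
from .ventilation import (BreathingWaveform, ResistanceModel,
                          assemble_and_solve)
from .washout import run_washout


@dataclass
class RunConfig:
    """Experiment description with the standard defaults."""

    # network source: a fixture kind, a file path, or generator params
    network_fixture: Optional[str] = "asymmetric_medium"
    network_file: Optional[str] = None
    n_terminal_target: Optional[int] = None
    seed: int = 0

    breath_s: float = 5.0
    tidal_ml: float = 625.0
    frc_l: float = 3.3
    e_total_cmh2o_per_l: float = 6.82
    dt_s: float = 0.01
    n_conditioning_breaths: int = 1
    resistance_mode: str = "poiseuille"

    particle_um: float = 4.0
    particle_density: float = 1000.0

    constriction_mode: Optional[str] = None   # lobar | clustered | random
    severity: float = 0.0
    lobe: str = "LU"
    n_clusters: int = 12
    cluster_radius_cm: float = 2.4
    count: int = 0
    constriction_seed: int = 0

    max_breaths: int = 60

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls().__dict__)
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        text = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(text.encode()).hexdigest()[:16]

    # ------------------------------------------------------------------
    def build_network(self) -> AirwayNetwork:
        if self.network_file:
            net = read_network(self.network_file,
                               e_total_cmh2o_per_l=self.e_total_cmh2o_per_l)
        elif self.n_terminal_target:
            net = generate_tree(
                GeneratorParams(n_terminal_target=self.n_terminal_target,
                                frc_l=self.frc_l,
                                e_total_cmh2o_per_l=self.e_total_cmh2o_per_l),
                seed=self.seed)
        else:
            net = make_fixture(self.network_fixture or "asymmetric_medium",
                               seed=self.seed)
        return net

    def build_pattern(self, net) -> Optional[con.ConstrictionPattern]:
        if not self.constriction_mode:
            return None
        if self.constriction_mode == "lobar":
            return con.lobar_pattern(net, self.lobe, self.severity)
        if self.constriction_mode == "clustered":
            return con.clustered_pattern(
                net, self.n_clusters, self.cluster_radius_cm * 1e-2,
                self.severity, seed=self.constriction_seed)
        if self.constriction_mode == "random":
            return con.random_pattern(net, self.count, self.severity,
                                      seed=self.constriction_seed)
        raise ValueError(
            f"unknown constriction mode {self.constriction_mode!r}")

    @property
    def waveform(self) -> BreathingWaveform:
        return BreathingWaveform(tb=self.breath_s, vt_l=self.tidal_ml / 1e3)

    @property
    def particle(self) -> ParticleProperties:
        return ParticleProperties(diameter=self.particle_um * 1e-6,
                                  density=self.particle_density)


def run_experiment(config: RunConfig, *, deposit: bool = True,
                   washout: bool = False) -> dict:
    """Execute generate -> (constrict) -> ventilate -> deposit/washout.

    Returns a bundle with the network, results and a manifest; the same
    config always yields byte-identical result tables.
    """
    from . import __version__

    t0 = time.time()
    net = config.build_network()
    pattern = config.build_pattern(net)
    if pattern is not None:
        net = con.apply(net, pattern)
    vent = assemble_and_solve(
        net, config.waveform,
        ResistanceModel(mode=config.resistance_mode),
        dt=config.dt_s, n_breaths=config.n_conditioning_breaths + 1)

    bundle: dict = {"net": net, "vent": vent, "pattern": pattern}
    if deposit:
        bundle["deposition"] = run_breath(net, vent, config.particle)
    if washout:
        bundle["washout"] = run_washout(net, vent, GasProperties(),
                                        max_breaths=config.max_breaths)
    bundle["manifest"] = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "version": __version__,
        "elapsed_s": round(time.time() - t0, 2),
    }
    return bundle


def severity_sweep(config: RunConfig, severities) -> "pd.DataFrame":
    """Deposition splits versus constriction severity (lobar pattern)."""
    import pandas as pd

    rows = []
    for sigma in severities:
        cfg = RunConfig(**{**asdict(config),
                           "constriction_mode": "lobar" if sigma > 0
                           else None,
                           "severity": float(sigma)})
        res = run_experiment(cfg)["deposition"]
        row = {"severity": float(sigma),
               "total": res.deposited_fraction, **res.splits()}
        rows.append(row)
    return pd.DataFrame(rows)
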