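"""Run configuration, artifact writing, and deterministic test fixtures.

Configuration lives in YAML with one section per component; empty sections
(or an empty file) fall back to the reference defaults: the Table of neuron
and synapse constants (g_E=0.005, g_I=0.11, V_Theta=-55 mV, tau_P=20 ms,
tau_ref=2 ms, ...), the two-component delay model, and the stimulation and
detection protocol constants. Unknown keys are rejected with their full path
so typos cannot silently fall back to defaults. Every artifact written
through ``write_artifacts`` records the configuration hash and is listed
with a checksum in a manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .engine import StimulusProtocol
from .network import DelayModel, EmbeddingConfig, build_control_chain, build_embedding
from .neurons import NeuronParams
from .packets import DetectionParams
from ._rng import stream_rng, stream_seed

__all__ = [
    "RunConfig", "GridConfig", "RunSettings", "ConfigError",
    "load_config", "dump_config", "write_artifacts", "make_fixture",
]

FIXTURE_NEURON_BUDGET = 50_000


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class GridConfig:
    """Sweep grids; the desk-scale defaults are deliberately coarse."""

    n_E: tuple = (60, 80, 112, 152, 200)
    lambda_E: tuple = (5.0, 10.0, 20.0, 40.0, 80.0, 160.0)
    trials: int = 20
    n_pools: int = 100

    @classmethod
    def paper_scale(cls) -> "GridConfig":
        return cls(
            n_E=tuple(range(20, 221, 4)),
            lambda_E=tuple(float(x) for x in range(1, 301)),
            trials=100,
            n_pools=100,
        )


@dataclass(frozen=True)
class RunSettings:
    duration: float = 1000.0
    dt: float = 0.1
    seed: int = 0
    background: tuple | None = None  # (lambda_E, lambda_I) kHz or None


@dataclass(frozen=True)
class RunConfig:
    neuron: NeuronParams = field(default_factory=NeuronParams)
    embedding: EmbeddingConfig = field(default_factory=lambda: EmbeddingConfig(C_E=500, n_E=32, N_E=5000))
    delays: DelayModel = field(default_factory=DelayModel)
    stimulus: StimulusProtocol = field(default_factory=StimulusProtocol)
    detection: DetectionParams = field(default_factory=DetectionParams)
    grids: GridConfig = field(default_factory=GridConfig)
    run: RunSettings = field(default_factory=RunSettings)

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(_as_plain(self), sort_keys=True).encode()
        ).hexdigest()[:12]


_SECTIONS = {
    "neuron": NeuronParams,
    "embedding": EmbeddingConfig,
    "delays": DelayModel,
    "stimulus": StimulusProtocol,
    "detection": DetectionParams,
    "grids": GridConfig,
    "run": RunSettings,
}


def _coerce(default, data: dict, path: str):
    """Overlay keys onto the section's default instance; reject unknowns."""
    names = {f.name for f in dataclasses.fields(default)}
    unknown = set(data) - names
    if unknown:
        key = sorted(unknown)[0]
        raise ConfigError(f"unknown configuration key '{path}.{key}'")
    kwargs = {
        k: (tuple(v) if isinstance(v, list) else v) for k, v in data.items()
    }
    try:
        return dataclasses.replace(default, **kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid section '{path}': {exc}") from exc


def load_config(path) -> RunConfig:
    """Parse a YAML run configuration; missing sections/keys take defaults."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("configuration root must be a mapping")
    unknown = set(raw) - set(_SECTIONS)
    if unknown:
        raise ConfigError(f"unknown configuration key '{sorted(unknown)[0]}'")
    defaults = RunConfig()
    kwargs = {
        name: _coerce(getattr(defaults, name), raw.get(name) or {}, name)
        for name in _SECTIONS
    }
    return RunConfig(**kwargs)


def _as_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _as_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (tuple, list)):
        return [_as_plain(x) for x in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def dump_config(config: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(_as_plain(config), sort_keys=False))


def write_artifacts(objects: dict, out_dir, config: RunConfig | None = None) -> dict:
    """Write named artifacts and a manifest with per-file SHA-256 checksums.

    Dispatch: objects with ``to_tsv``/``save`` use their own writers; plain
    mappings/arrays become JSON.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = {}
    for name, obj in objects.items():
        if hasattr(obj, "to_tsv"):
            fname = f"{name}.tsv"
            obj.to_tsv(out / fname)
        elif hasattr(obj, "save"):
            fname = f"{name}.npz" if "Network" in type(obj).__name__ else name
            obj.save(out / fname)
        else:
            fname = f"{name}.json"
            (out / fname).write_text(json.dumps(_as_plain(obj), indent=1))
        digest = hashlib.sha256((out / fname).read_bytes()).hexdigest()
        entries[fname] = digest
    manifest = {
        "files": entries,
        "config_hash": config.content_hash() if config else None,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def make_fixture(kind: str, params: dict | None = None, seed: int = 0):
    """Deterministic synthetic inputs for tests.

    Kinds: ``raster_with_packets`` (per-pool spike trains with planted
    packets at known times over sparse background), ``tiny_embedding`` (a
    miniature ring embedding), ``control_chain`` (a short feedforward chain).
    Requests beyond the desk-scale neuron budget are refused.
    """
    p = dict(params or {})
    if kind == "raster_with_packets":
        n_pools = int(p.pop("n_pools", 10))
        n_E = int(p.pop("n_E", 100))
        duration = float(p.pop("duration", 1000.0))
        bg_rate = float(p.pop("background_Hz", 2.0))  # per neuron
        packet_frac = float(p.pop("packet_frac", 0.85))
        gap = float(p.pop("gap_ms", 3.0))
        start = float(p.pop("start_ms", 100.0))
        if p:
            raise ConfigError(f"unknown fixture parameter {sorted(p)[0]!r}")
        if n_pools * n_E > FIXTURE_NEURON_BUDGET:
            raise ConfigError(
                "fixture over neuron budget; reduce n_pools or n_E "
                f"below {FIXTURE_NEURON_BUDGET} total neurons"
            )
        rng = stream_rng(seed, "fixture-raster")
        planted = {mu: start + gap * mu for mu in range(n_pools)}
        rasters = {}
        size = int(round(packet_frac * n_E))
        for mu in range(n_pools):
            n_bg = rng.poisson(bg_rate * n_E * duration / 1000.0)
            bg = rng.uniform(0, duration, size=n_bg)
            pk = rng.normal(planted[mu], 0.2, size=size)
            rasters[mu] = np.sort(np.concatenate([bg, pk]))
        return {"rasters": rasters, "planted_times": planted,
                "planted_size": size, "n_E": n_E}
    if kind == "tiny_embedding":
        cfg = EmbeddingConfig(
            C_E=int(p.pop("C_E", 500)),
            n_E=int(p.pop("n_E", 32)),
            N_E=int(p.pop("N_E", 5000)),
            seed=seed,
        )
        if p:
            raise ConfigError(f"unknown fixture parameter {sorted(p)[0]!r}")
        total = cfg.N_E_effective * (1 + cfg.gamma)
        if total > FIXTURE_NEURON_BUDGET:
            raise ConfigError(
                "fixture over neuron budget; try N_E <= "
                f"{int(FIXTURE_NEURON_BUDGET / (1 + cfg.gamma))}"
            )
        return build_embedding(cfg, DelayModel(), seed=stream_seed(seed, "fixture-net"))
    if kind == "control_chain":
        n_E = int(p.pop("n_E", 50))
        n_pools = int(p.pop("n_pools", 20))
        if p:
            raise ConfigError(f"unknown fixture parameter {sorted(p)[0]!r}")
        if n_E * n_pools > FIXTURE_NEURON_BUDGET:
            raise ConfigError("fixture over neuron budget; reduce the chain")
        return build_control_chain(n_E, n_pools, DelayModel(), seed=stream_seed(seed, "fixture-chain"))
    raise ConfigError(f"unknown fixture kind {kind!r}")
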