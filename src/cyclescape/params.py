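"""Model parameters for the three-node budding-yeast cell-cycle network.

The deterministic model tracks three lumped regulators:

* ``x`` — G1/S module (Cln1,2 / Clb5,6 cyclins, SBF/MBF),
* ``y`` — early-M module (Clb1,2, Mcm1/SFF),
* ``z`` — late-M/G1 inhibitors (Cdh1, Cdc20, Sic1),

each with a second-order Hill positive feedback, linear degradation, a
bilinear repression from the next module and a linear trigger from the
previous one.  ``a0`` is the nutrient-dependent basal production of ``x``.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace
from pathlib import Path
from typing import Mapping

import yaml

__all__ = ["ModelParams", "baseline_params", "preset", "PRESETS", "load_params"]

PARAM_NAMES = ("j1", "j2", "j3", "k1", "k2", "k3", "ki", "ks", "ka1", "ka2", "a0")


@dataclass(frozen=True)
class ModelParams:
    """Rate and threshold constants of the three-module network.

    Units: concentrations are dimensionless model units; ``j*`` are Hill
    half-saturation concentrations, ``k1..k3`` degradation rates (1/time),
    ``ki`` the strength of z's inhibition of x (1/(conc·time)), ``ks`` the
    saturated synthesis rate of z (conc/time), ``ka1``/``ka2`` trigger
    coupling rates (1/time) and ``a0`` basal nutrient-driven production of
    x (conc/time).
    """

    j1: float = 0.5
    j2: float = 0.5
    j3: float = 0.5
    k1: float = 0.2
    k2: float = 0.2
    k3: float = 0.2
    ki: float = 5.0
    ks: float = 1.0
    ka1: float = 0.001
    ka2: float = 0.001
    a0: float = 0.001

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            v = getattr(self, name)
            if not (v > 0):
                raise ValueError(f"parameter {name} must be strictly positive, got {v!r}")

    def as_dict(self) -> dict[str, float]:
        return asdict(self)

    def with_updates(self, **updates: float) -> "ModelParams":
        unknown = set(updates) - set(PARAM_NAMES)
        if unknown:
            raise KeyError(f"unknown parameters: {sorted(unknown)}")
        return replace(self, **updates)


def baseline_params() -> ModelParams:
    """Baseline parameter set (excitable regime, poor nutrients)."""
    return ModelParams()


#: Named presets.  Each differs from baseline in exactly the printed edits:
#: richer medium raises a0; an activated DNA-replication (S) checkpoint
#: lowers the x→y trigger ka1; an activated M checkpoint lowers ka2.
PRESETS: Mapping[str, dict[str, float]] = {
    "baseline": {},
    "rich_nutrient": {"a0": 0.01},
    "s_checkpoint": {"ka1": 0.0001},
    "m_checkpoint": {"ka2": 0.0001},
}


def preset(name: str) -> ModelParams:
    try:
        edits = PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}") from None
    return baseline_params().with_updates(**edits)


def load_params(source: str | Path | Mapping[str, object]) -> ModelParams:
    """Load parameters from a mapping or a YAML / ``key = value`` text file.

    A ``preset`` key selects a named preset; any further keys override
    individual parameters.
    """
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
        try:
            data = yaml.safe_load(text)
        except yaml.YAMLError:
            data = None
        if not isinstance(data, dict):  # fall back to key = value lines
            data = {}
            for line in text.splitlines():
                line = line.split("#")[0].strip()
                if not line:
                    continue
                key, _, value = line.partition("=")
                data[key.strip()] = float(value)
    else:
        data = dict(source)
    base = preset(str(data.pop("preset"))) if "preset" in data else baseline_params()
    return base.with_updates(**{k: float(v) for k, v in data.items()})
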