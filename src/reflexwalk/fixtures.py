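"""Shipped optimized reflex-parameter fixtures and experiment setups.

One CMA-ES-optimized parameter set is versioned per target walking speed
(0.83, 0.97, 1.11 and 1.20 m/s — the speeds of the five replicated
disturbance experiments) so disturbance trials and analyses run in minutes
instead of requiring a fresh gait optimization.

Experiment table (subject anthropometry and walking speed; height/weight
default to 1.80 m / 80 kg where the source study reports none):

====== ======= ====== ============
proto  height  mass   speed [m/s]
====== ======= ====== ============
MMR    1.75    64     0.97
TR     1.80    80     0.83
SR     1.80    80     0.97
TRIP   1.80    80     1.11
SLIP   1.80    75     1.20
====== ======= ====== ============
"""

from __future__ import annotations

from importlib import resources

from .control import ReflexParameters
from .walker import ReflexWalker

__all__ = ["SPEEDS", "EXPERIMENTS", "fixture_params", "experiment_setup"]

SPEEDS = (0.83, 0.97, 1.11, 1.20)

EXPERIMENTS = {
    "MMR": {"height": 1.75, "mass": 64.0, "speed": 0.97},
    "TR": {"height": 1.80, "mass": 80.0, "speed": 0.83},
    "SR": {"height": 1.80, "mass": 80.0, "speed": 0.97},
    "TRIP": {"height": 1.80, "mass": 80.0, "speed": 1.11},
    "SLIP": {"height": 1.80, "mass": 75.0, "speed": 1.20},
}


def fixture_params(speed: float) -> ReflexParameters:
    """Load the shipped optimized parameter set for a target speed."""
    key = f"{speed:.2f}".replace(".", "")
    name = f"params_{key}.txt"
    ref = resources.files("reflexwalk.data").joinpath(name)
    if not ref.is_file():
        raise FileNotFoundError(
            f"no fixture parameter set for v = {speed} m/s (expected {name})")
    with resources.as_file(ref) as path:
        return ReflexParameters.load(path)


def experiment_setup(protocol: str, dt: float = 5e-4):
    """Walker, optimized parameters and target speed for one experiment.

    The reflex parameters are optimized on the default 1.80 m / 80 kg
    model at the experiment's speed; they are expressed in normalized
    (dimensionless) afferent units and remain stable under the
    anthropometric scalings of the experiment table (the realized average
    speed shifts by up to ~0.05 m/s on the rescaled bodies).
    """
    cfg = EXPERIMENTS[protocol]
    walker = ReflexWalker(height=cfg["height"], mass=cfg["mass"], dt=dt)
    params = fixture_params(cfg["speed"])
    return walker, params, cfg["speed"]
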