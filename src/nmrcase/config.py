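"""Solver configuration: spectral windows, kernel widths, search sizes.

All tunables of the pipeline live here so that a database build, a
retrieval run and an optimization run can be reproduced from a single
frozen object.  The spectral parameters that affect how a database is
encoded (windows, encoding sigmas, grid size, predictor identity) are
hashed into ``spectral_hash`` and stored with the database on disk;
loading a database with a different hash is refused.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

#: number of grid samples per nucleus in the encoded spectrum
N_GRID = 128


@dataclass(frozen=True)
class SpectrumConfig:
    """Encoding and matching parameters for the two nuclei.

    Windows cover the conventional chemical-shift ranges; encoding sigmas
    are about one grid spacing so adjacent samples overlap smoothly, and
    the (tighter) matching sigmas are commensurate with the ppm scale of
    forward-prediction error.
    """

    h_window: tuple[float, float] = (-2.0, 16.0)
    c_window: tuple[float, float] = (-10.0, 230.0)
    n_grid: int = N_GRID
    sigma_encode_h: float = 0.2
    sigma_encode_c: float = 2.0
    sigma_match_h: float = 0.1
    sigma_match_c: float = 1.0
    weight_h: float = 0.5
    weight_c: float = 0.5
    #: kernel multiplier for contradictory multiplicity tags (hook; off by default)
    multiplicity_penalty: float = 0.5
    use_multiplicity_weights: bool = False


@dataclass(frozen=True)
class SolverConfig:
    """Full configuration of retrieval and fragment-based optimization."""

    spectrum: SpectrumConfig = field(default_factory=SpectrumConfig)
    # two-stage retrieval
    k_ann: int = 200
    k_final: int = 20
    # fragment-pair selection stages
    k_frag: int = 10      # complementary partners retrieved per fragment (stage 1)
    m_pairs: int = 500    # pairs kept after global vector re-rank (stage 2)
    k_refine: int = 50    # pairs refined by set similarity (stage 3)
    # pool / loop control
    pool_size: int = 50
    max_iterations: int = 5
    patience: int = 2
    # constraints
    allowed_elements: tuple[str, ...] | None = None
    formula: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("k_ann", "k_final", "k_frag", "m_pairs", "k_refine",
                     "pool_size", "max_iterations", "patience"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


def spectral_hash(cfg: SpectrumConfig, predictor_id: str) -> str:
    """Short hash identifying an encoding scheme + predictor combination."""
    payload = {"predictor": predictor_id, **asdict(cfg)}
    blob = json.dumps(payload, sort_keys=True).encode()
    return hashlib.sha1(blob).hexdigest()[:16]
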