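"""Model input/output surface: on-disk dialect, fixtures, random networks.

Convenience namespace collecting the container types (:mod:`selfcell.model`),
the JSON/TSV readers and writers (:mod:`selfcell.io`) and the reference
networks (:mod:`selfcell.fixtures`).
"""

from .fixtures import (
    TOY_BIOMASS_FRACTIONS,
    TOY_WEIGHTS,
    fixture_internal_network,
    fixture_toy_network,
    fixture_unit_network,
    generate_random_conservative_network,
)
from .io import (
    ModelFormatError,
    load_matrix_tsv,
    load_model,
    load_solution,
    save_model,
    save_solution,
)
from .model import Compound, ModelValidationError, Network, Reaction

__all__ = [
    "Compound",
    "Reaction",
    "Network",
    "ModelValidationError",
    "ModelFormatError",
    "load_model",
    "save_model",
    "load_matrix_tsv",
    "save_solution",
    "load_solution",
    "fixture_toy_network",
    "fixture_internal_network",
    "fixture_unit_network",
    "generate_random_conservative_network",
    "TOY_WEIGHTS",
    "TOY_BIOMASS_FRACTIONS",
]
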