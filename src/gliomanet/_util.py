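"""Small shared helpers: seeding, validation errors."""

from __future__ import annotations

import zlib


class ParameterError(ValueError):
    """A parameter is outside its documented domain."""


class InputError(ValueError):
    """An input object violates a documented precondition."""


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a per-stage RNG seed from a single global seed.

    Stable across runs and platforms (CRC32 of the stage name), and kept
    below 2**31 so it is valid for every RNG the package uses.  Toggling
    one stage never perturbs another stage's stream.
    """
    return (int(global_seed) * 0x9E3779B1 + zlib.crc32(stage.encode())) % (2**31 - 1)
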