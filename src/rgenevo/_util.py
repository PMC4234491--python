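"""Small shared helpers: seed partitioning and error types."""

from __future__ import annotations

import hashlib


class RgenevoError(Exception):
    """Base class for package errors."""


class ParseError(RgenevoError):
    """An input file violated its format contract."""


class FixtureError(RgenevoError):
    """A packaged fixture failed its integrity check."""


def seed_for(seed: int, stage: str) -> int:
    """Derive a per-stage RNG seed from one master seed.

    Stage streams are independent of each other and stable under the addition
    of new stages (hash of the stage name, folded with the master seed); the
    result is kept below 2**31 so it is portable across RNG back ends.
    """
    h = hashlib.blake2b(f"{seed}:{stage}".encode(), digest_size=8).digest()
    return int.from_bytes(h, "little") % (2**31 - 1)
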