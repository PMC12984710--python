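"""Shared constants and seeding utilities.

The three diagnostic classes are ordered (normal, drusen, cnv) everywhere:
probability columns, confusion-matrix axes and tie-breaking all follow this
order.
"""

from __future__ import annotations

import hashlib
import logging

import numpy as np

logger = logging.getLogger("oct_its")

#: Canonical class order: healthy retina, dry-AMD drusen deposits, wet-AMD
#: choroidal neovascularization.
CLASSES: tuple[str, str, str] = ("normal", "drusen", "cnv")

CLASS_TO_INDEX: dict[str, int] = {c: i for i, c in enumerate(CLASSES)}

#: Sentinel label for records whose class is unknown (real-data adapters) or
#: deliberately hidden (semi-supervised training pools).
UNLABELED = "UNLABELED"


def child_seed(seed: int, *names: object) -> int:
    """Derive a named, stable sub-seed below 2**31 from a root seed.

    Named substreams keep the split, subset, initialization and rendering
    randomness decoupled: changing how one consumer draws numbers cannot
    perturb another.
    """
    key = f"{int(seed)}/" + "/".join(str(n) for n in names)
    digest = hashlib.blake2b(key.encode("utf-8"), digest_size=4).digest()
    return int.from_bytes(digest, "big") % (2**31)


def check_labels(labels) -> None:
    """Raise ``ValueError`` naming the first token outside the class set."""
    for lab in labels:
        if lab not in CLASS_TO_INDEX:
            raise ValueError(f"unknown class label: {lab!r}")


def encode_labels(labels) -> np.ndarray:
    check_labels(labels)
    return np.asarray([CLASS_TO_INDEX[lab] for lab in labels], dtype=np.int64)
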