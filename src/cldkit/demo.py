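"""Shipped single-group demo CLD.

A transcription of a published workshop group's narrated feedback loops
around dementia risk: the trauma / substance-abuse / domestic-violence
reinforcing triangle, a health-literacy information loop, criminal-justice
and caregiving loops, a discriminatory-policy loop, and two balancing
caregiving/stigma loops, plus two action-idea nodes (an information
campaign and voter mobilization).

Two narrated loop labels describe open chains that feed other loops rather
than closed cycles, and the narrated signs of the policy loop carry an even
number of negative links; the transcription records the narrated edges
as-is and lets the parity rule classify whatever cycles actually exist.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .io import read_group_models
from .model import GroupModel, canonicalize_labels

__all__ = ["DEMO_FOCAL", "demo_path", "load_demo_models"]

DEMO_FOCAL = "dementia"


def demo_path() -> Path:
    """Filesystem path of the shipped demo edge list."""
    return Path(resources.files("cldkit.data") / "demo_workshop.csv")


def load_demo_models() -> list[GroupModel]:
    """The demo CLD as a canonicalized single-element model list."""
    with demo_path().open(newline="", encoding="utf-8") as handle:
        models = read_group_models(handle, focal_label=DEMO_FOCAL)
    return canonicalize_labels(models)
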