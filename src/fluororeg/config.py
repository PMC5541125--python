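"""Shipped default configurations (C-arm, fiducial geometry, noise profiles)."""

from __future__ import annotations

import json
from importlib import resources

from .geometry import CArmModel


def _data(name: str) -> dict:
    with resources.files("fluororeg.data").joinpath(name).open() as fh:
        return json.load(fh)


def default_carm() -> CArmModel:
    """The shipped C-arm model: 230-mm intensifier, SID 980 mm, 0.224 mm/px."""
    return CArmModel.from_dict(_data("carm_default.json"))


def default_fiducial():
    """The shipped registration-tool geometry (3 beads + pin tip)."""
    from .fiducial import FiducialGeometry

    return FiducialGeometry.from_dict(_data("fiducial_default.json"))


def noise_profile(name: str) -> dict:
    """A named synthesis noise profile: ``clean``, ``phantom-like`` or ``cadaver-like``."""
    key = name.replace("-", "_").replace(" ", "_")
    try:
        return _data(f"profile_{key}.json")
    except FileNotFoundError:
        raise KeyError(f"unknown noise profile {name!r}") from None
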