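"""Registry of cardiac action-potential cell models.

Registered models: ``beeler_reuter_1977``, ``luo_rudy_1991``,
``tentusscher_2004`` (epicardial) and ``tentusscher_2006_epi``.
More detailed models (e.g. O'Hara 2011, Davies 2012 canine) can be added as
plug-ins via :func:`register_model`; they are not transcribed here.
"""

from __future__ import annotations

from .base import CellModel, Conditions, ParameterVector, scale_conductances
from . import beeler_reuter, luo_rudy, tentusscher_2004, tentusscher_2006_epi

__all__ = [
    "CellModel",
    "Conditions",
    "ParameterVector",
    "scale_conductances",
    "get_model",
    "register_model",
    "available_models",
]

_BUILDERS = {
    "beeler_reuter_1977": beeler_reuter.build,
    "luo_rudy_1991": luo_rudy.build,
    "tentusscher_2004": tentusscher_2004.build,
    "tentusscher_2006_epi": tentusscher_2006_epi.build,
}
_CACHE: dict[str, CellModel] = {}


def available_models() -> list[str]:
    return sorted(_BUILDERS)


def register_model(name: str, builder) -> None:
    """Register a plug-in model builder under ``name``."""
    _BUILDERS[name] = builder
    _CACHE.pop(name, None)


def get_model(name: str) -> CellModel:
    """Return a registered model by name.

    Raises ``KeyError`` listing the registry for unknown names.
    """
    if name not in _BUILDERS:
        raise KeyError(f"unknown model {name!r}; registered models: {available_models()}")
    if name not in _CACHE:
        _CACHE[name] = _BUILDERS[name]()
    return _CACHE[name]
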