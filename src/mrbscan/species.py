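"""Default ion tables for the electromigration simulator."""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import yaml

from .errors import ConfigurationError
from .forward import IonSpecies


def load_species_table(path: str | Path | None = None) -> dict[str, IonSpecies]:
    """Load an ion parameter table (name -> IonSpecies) from YAML.

    With no path, the packaged literature defaults are used.  Each entry needs
    ``charge_sign``, ``mobility`` and ``diffusion_coeff``; reservoir
    concentrations (``init_conc_left``/``init_conc_right``, mol/m^3) are
    optional and default to zero.
    """
    if path is None:
        text = (
            resources.files("mrbscan").joinpath("data/ion_defaults.yaml").read_text()
        )
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ConfigurationError("species table must be a mapping of name -> params")
    table: dict[str, IonSpecies] = {}
    for name, params in raw.items():
        if not isinstance(params, dict):
            raise ConfigurationError(f"species {name!r}: parameters must be a mapping")
        try:
            table[name] = IonSpecies(
                name=name,
                charge_sign=int(params["charge_sign"]),
                mobility=float(params["mobility"]),
                diffusion_coeff=float(params["diffusion_coeff"]),
                init_conc_left=float(params.get("init_conc_left", 0.0)),
                init_conc_right=float(params.get("init_conc_right", 0.0)),
            )
        except KeyError as exc:
            raise ConfigurationError(
                f"species {name!r} lacks required field {exc}"
            ) from exc
    return table


def default_species(*names: str) -> list[IonSpecies]:
    """Packaged default species, optionally restricted to ``names`` (in order)."""
    table = load_species_table()
    if not names:
        return list(table.values())
    try:
        return [table[n] for n in names]
    except KeyError as exc:
        raise ConfigurationError(f"no default parameters for species {exc}") from exc
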