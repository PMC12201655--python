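"""Model constants and species definitions.

The simulator is controlled by a single flat set of named constants: per-step
event probabilities (``P_*``), dimensionless modifier factors (``F_*``), grid
and material totals, and two structural lengths (``L_AM``, the minimum number
of amphiphile tails needed to close a membrane, and ``L_CDR``, the length of
the characteristic domain that gives an RNA strand its function).  Every
constant has a documented default; a configuration file only needs to list
the values it overrides.

Configuration dialect
---------------------
A config is a flat YAML mapping whose keys are the constant names used
throughout the model (``P_FLM: 0.002``) plus optional ``SEQ_<NAME>`` entries
overriding the characteristic sequence of a species (``SEQ_GR: CCAUGUA``).
Unknown keys are rejected, as are out-of-range values.
"""

from __future__ import annotations

import dataclasses
import io
import numbers
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, TextIO

import numpy as np
import yaml

__all__ = [
    "ParameterSet",
    "SpeciesDef",
    "ValidationReport",
    "ConfigError",
    "load_params",
    "validate_params",
    "dump_params",
    "default_species",
    "PARAM_ORDER",
    "DEFAULTS",
]


class ConfigError(ValueError):
    """Raised for unparsable configs, unknown keys or out-of-range values."""


#: Names of all per-step event probabilities, alphabetically.
PROBABILITY_NAMES = (
    "P_AT", "P_BB", "P_CB", "P_CD", "P_CF", "P_FJM", "P_FLM", "P_FP",
    "P_GD", "P_GF", "P_GFR", "P_GPP", "P_MC", "P_MF", "P_MV", "P_ND",
    "P_NDE", "P_NF", "P_NFR", "P_NP", "P_NPD", "P_NPF", "P_NPFR", "P_NPP",
    "P_NPPP", "P_PD", "P_PDM", "P_PF", "P_PJM", "P_PLM", "P_RL", "P_SP",
    "P_TL",
)

#: Non-probability constants (grid size, totals, factors, lengths).
OTHER_NAMES = (
    "N", "T_NPPB", "T_FB", "T_GPB",
    "F_DE", "F_DO", "F_PL", "F_PP", "F_PPW", "F_TR",
    "L_AM", "L_CDR", "L_TMIN",
)

PARAM_ORDER = PROBABILITY_NAMES + OTHER_NAMES

DEFAULTS: dict[str, float] = {
    # event probabilities
    "P_AT": 0.9,        # template attracts a substrate
    "P_BB": 1e-5,       # phosphodiester bond breaking
    "P_CB": 1e-4,       # protocell breaking
    "P_CD": 0.1,        # protocell dividing
    "P_CF": 0.001,      # two adjacent protocells fusing
    "P_FJM": 0.9,       # fatty acid joining the membrane
    "P_FLM": 0.002,     # fatty acid leaving the membrane
    "P_FP": 0.001,      # false base-pairing during attraction
    "P_GD": 0.1,        # glycerophosphate decaying to its precursor
    "P_GF": 0.002,      # glycerophosphate forming, non-enzymatic
    "P_GFR": 0.9,       # glycerophosphate forming, catalyzed by GR
    "P_GPP": 0.9,       # glycerophosphate precursor permeating
    "P_MC": 0.1,        # protocell moving
    "P_MF": 0.1,        # membrane forming
    "P_MV": 0.9,        # small molecule moving
    "P_ND": 0.02,       # nucleotide decaying to its precursor
    "P_NDE": 0.001,     # chain-end nucleotide residue decaying
    "P_NF": 0.005,      # nucleotide forming, non-enzymatic
    "P_NFR": 0.2,       # nucleotide forming, catalyzed by NR
    "P_NP": 5e-5,       # nucleotide permeating
    "P_NPD": 0.005,     # nucleotide precursor decaying
    "P_NPF": 0.002,     # nucleotide precursor forming, non-enzymatic
    "P_NPFR": 0.3,      # nucleotide precursor forming, catalyzed by NPR
    "P_NPP": 0.05,      # nucleotide precursor permeating
    "P_NPPP": 0.5,      # nucleotide-precursor's precursor permeating
    "P_PD": 0.1,        # free phospholipid decaying
    "P_PDM": 0.01,      # membrane phospholipid decaying
    "P_PF": 0.02,       # phospholipid forming on the membrane
    "P_PJM": 0.9,       # phospholipid joining the membrane
    "P_PLM": 1e-4,      # phospholipid leaving the membrane
    "P_RL": 1e-6,       # random ligation
    "P_SP": 0.5,        # separation of one base pair
    "P_TL": 0.2,        # template-directed ligation
    # grid and material totals
    "N": 30,            # grid side length (rooms)
    "T_NPPB": 80000,    # initial nucleotide-precursor's precursors
    "T_FB": 50000,      # initial fatty acids
    "T_GPB": 50000,     # initial glycerophosphate precursors
    # dimensionless factors
    "F_DE": 1.0,        # Donnan's-equilibrium effect
    "F_DO": 10.0,       # degradation enhancement outside protocells
    "F_PL": 5.0,        # phospholipid influence on amphiphile efflux
    "F_PP": 20.0,       # phospholipid influence on Nt/Np permeability
    "F_PPW": 3.0,       # weak version, for Npp and Gp
    "F_TR": 100.0,      # strength of TR-mediated transport
    # structural lengths
    "L_AM": 200,        # minimum amphiphile tails to form a membrane
    "L_CDR": 7,         # characteristic-domain length (nt)
    "L_TMIN": 7,        # shortest chain able to act as a template (nt)
}

_INT_NAMES = {"N", "T_NPPB", "T_FB", "T_GPB", "L_AM", "L_CDR", "L_TMIN"}

#: Enumerated functions a characteristic domain can confer.
FUNCTIONS = (
    "none",                          # control species
    "glycerophosphate_synthetase",   # GR: catalyzes Gp -> G
    "nucleotide_synthetase",         # NR: catalyzes Np -> Nt
    "nucleotide_precursor_synthetase",  # NPR: catalyzes Npp -> Np
    "transport_enhancer",            # TR: raises Np membrane permeability
)

_DEFAULT_SPECIES = (
    ("GR", "UUGAGCG", "glycerophosphate_synthetase"),
    ("NR", "GCACGUA", "nucleotide_synthetase"),
    ("NPR", "UCACGAG", "nucleotide_precursor_synthetase"),
    ("TR", "CUGCUAG", "transport_enhancer"),
    ("CTL", "GGCUACU", "none"),
)

ALPHABET = "ACGU"


@dataclass(frozen=True)
class SpeciesDef:
    """An RNA functional species: a name, a characteristic domain, a function.

    Any strand containing ``domain`` as a contiguous substring counts as a
    molecule of this species; a free (non-duplexed) such strand exerts the
    species' catalytic or transport function in its compartment.
    """

    name: str
    domain: str
    function: str = "none"

    def __post_init__(self) -> None:
        if self.function not in FUNCTIONS:
            raise ValueError(f"unknown function {self.function!r} for species {self.name}")
        bad = set(self.domain) - set(ALPHABET)
        if bad:
            raise ValueError(f"species {self.name}: domain contains non-RNA symbols {sorted(bad)}")
        if len(self.domain) < 1:
            raise ValueError(f"species {self.name}: empty domain")


def default_species(p: "ParameterSet | None" = None,
                    overrides: Mapping[str, str] | None = None) -> list[SpeciesDef]:
    """The five standard species (GR, NR, NPR, TR, control).

    ``overrides`` maps species names to replacement characteristic sequences
    (used e.g. when GR is given a domain only two bases away from NR's).
    """
    overrides = overrides or {}
    lcdr = int(p.L_CDR) if p is not None else int(DEFAULTS["L_CDR"])
    out = []
    for name, domain, func in _DEFAULT_SPECIES:
        domain = overrides.get(name, domain)
        if len(domain) != lcdr:
            raise ConfigError(
                f"species {name}: domain {domain!r} has length {len(domain)}, expected L_CDR={lcdr}")
        out.append(SpeciesDef(name, domain, func))
    return out


def _make_field(name: str):
    default = DEFAULTS[name]
    if name in _INT_NAMES:
        return (name, int, field(default=int(default)))
    return (name, float, field(default=float(default)))


ParameterSet = dataclasses.make_dataclass(
    "ParameterSet",
    [_make_field(n) for n in PARAM_ORDER],
    namespace={
        "__doc__": (
            "The full constant set controlling one simulation.  Fields are the\n"
            "symbols of the model: per-step probabilities P_*, factors F_*, the\n"
            "grid side N, initial totals T_*, and lengths L_AM / L_CDR.\n"
            "Construct via load_params() or ParameterSet(**overrides)."
        ),
    },
)


def _ps_replace(self, **changes):
    return dataclasses.replace(self, **changes)


def _ps_to_dict(self) -> dict:
    return {n: getattr(self, n) for n in PARAM_ORDER}


def _ps_as_vector(self) -> np.ndarray:
    """Dense float64 view in PARAM_ORDER, consumed by the step kernels."""
    return np.array([float(getattr(self, n)) for n in PARAM_ORDER], dtype=np.float64)


ParameterSet.replace = _ps_replace
ParameterSet.to_dict = _ps_to_dict
ParameterSet.as_vector = _ps_as_vector

#: Index of each constant in the kernel parameter vector.
PARAM_INDEX = {n: i for i, n in enumerate(PARAM_ORDER)}


@dataclass
class ValidationReport:
    """Outcome of validate_params: hard bound violations and soft warnings."""

    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def __bool__(self) -> bool:  # truthy iff valid
        return self.ok


#: Ordering rules the default constants obey ("catalyzed must beat
#: non-enzymatic", "self-assembly beats disassembly", ...).  Violations are
#: reported as warnings, not errors, because deliberately breaking one is how
#: knockout experiments are run.
ORDERING_RULES = (
    ("P_NFR", ">", "P_NF"),
    ("P_GFR", ">", "P_GF"),
    ("P_NPFR", ">", "P_NPF"),
    ("P_TL", ">", "P_RL"),
    ("P_NDE", "<", "P_ND"),
    ("P_NPPP", ">", "P_NPP"),
    ("P_NPP", ">", "P_NP"),
    ("P_MF", ">", "P_CB"),
    ("P_FJM", ">", "P_FLM"),
    ("P_PJM", ">", "P_PLM"),
    ("P_PLM", "<", "P_FLM"),
    ("P_PDM", "<", "P_PD"),
    ("P_MV", ">", "P_MC"),
    ("F_DO", ">", 1.0),
    ("F_PPW", "<", "F_PP"),
)


def validate_params(p) -> ValidationReport:
    """Check hard bounds and the soft ordering rules of the model.

    Hard bounds (violations are errors): probabilities in [0, 1], factors
    >= 0, N >= 2, L_AM >= 1, L_CDR >= 1, totals >= 0.  The ordering rules
    (e.g. ``P_GFR > P_GF``) express that catalysis, self-assembly and inside
    protection must dominate for the model's regime; breaking one produces a
    warning only, so that knockout runs remain expressible.
    """
    rep = ValidationReport()
    for name in PROBABILITY_NAMES:
        v = getattr(p, name)
        if not (0.0 <= v <= 1.0):
            rep.errors.append(f"{name}={v!r} outside [0, 1]")
    for name in ("F_DE", "F_DO", "F_PL", "F_PP", "F_PPW", "F_TR"):
        v = getattr(p, name)
        if v < 0:
            rep.errors.append(f"{name}={v!r} must be >= 0")
    if p.N < 2:
        rep.errors.append(f"N={p.N!r} must be >= 2")
    if p.L_AM < 1:
        rep.errors.append(f"L_AM={p.L_AM!r} must be >= 1")
    if p.L_CDR < 1:
        rep.errors.append(f"L_CDR={p.L_CDR!r} must be >= 1")
    if p.L_TMIN < 1:
        rep.errors.append(f"L_TMIN={p.L_TMIN!r} must be >= 1")
    for name in ("T_NPPB", "T_FB", "T_GPB"):
        if getattr(p, name) < 0:
            rep.errors.append(f"{name} must be >= 0")
    for lhs, op, rhs in ORDERING_RULES:
        a = getattr(p, lhs)
        b = getattr(p, rhs) if isinstance(rhs, str) else rhs
        ok = a > b if op == ">" else a < b
        if not ok:
            rhs_s = rhs if isinstance(rhs, str) else repr(rhs)
            rep.warnings.append(f"ordering rule violated: expected {lhs} {op} {rhs_s} "
                                f"(got {lhs}={a!r}, {rhs_s}={b!r})")
    return rep


def _read_source(source) -> Mapping:
    if source is None:
        return {}
    if isinstance(source, Mapping):
        return source
    if isinstance(source, os.PathLike):
        with open(source) as fh:
            text = fh.read()
    elif isinstance(source, io.IOBase) or hasattr(source, "read"):
        text = source.read()
    elif isinstance(source, str):
        # a path if it names an existing file, else literal config text
        if "\n" not in source and os.path.exists(source):
            with open(source) as fh:
                text = fh.read()
        else:
            text = source
    else:
        raise ConfigError(f"unsupported config source type {type(source).__name__}")
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"config parse failure: {exc}") from exc
    if data is None:
        return {}
    if not isinstance(data, Mapping):
        raise ConfigError("config must be a flat key: value mapping")
    return data


def load_params(source=None) -> tuple["ParameterSet", list[SpeciesDef]]:
    """Load a parameter set and species list from a flat key/value config.

    ``source`` may be None (pure defaults), a mapping, YAML text, a path or
    an open file.  Keys are the model constant names, plus ``SEQ_GR`` /
    ``SEQ_NR`` / ``SEQ_NPR`` / ``SEQ_TR`` / ``SEQ_CTL`` for characteristic
    sequences.  Any omitted key keeps its default.  Unknown keys and
    out-of-range values raise :class:`ConfigError` naming the offending key.
    """
    data = _read_source(source)
    seq_keys = {f"SEQ_{name}": name for name, _, _ in _DEFAULT_SPECIES}
    values: dict[str, float] = {}
    seq_overrides: dict[str, str] = {}
    for key, raw in data.items():
        if key in seq_keys:
            if not isinstance(raw, str):
                raise ConfigError(f"{key}: expected a base string, got {raw!r}")
            seq_overrides[seq_keys[key]] = raw.strip().upper()
        elif key in PARAM_INDEX:
            if not isinstance(raw, numbers.Real) or isinstance(raw, bool):
                raise ConfigError(f"{key}: expected a number, got {raw!r}")
            values[key] = int(raw) if key in _INT_NAMES else float(raw)
        else:
            raise ConfigError(f"unknown key {key!r}")
    p = ParameterSet(**values)
    rep = validate_params(p)
    if not rep.ok:
        raise ConfigError("; ".join(rep.errors))
    species = default_species(p, seq_overrides)
    return p, species


def dump_params(p, species: Iterable[SpeciesDef] | None = None,
                stream: TextIO | None = None) -> str:
    """Serialize a parameter set (and optional species sequences) as config text.

    Round-trips through :func:`load_params`.
    """
    data: dict[str, object] = {n: getattr(p, n) for n in PARAM_ORDER}
    if species is not None:
        data.update({f"SEQ_{s.name}": s.domain for s in species})
    text = yaml.safe_dump(data, sort_keys=False, default_flow_style=False)
    if stream is not None:
        stream.write(text)
    return text
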