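"""Structured model definitions and their compilation to simulable right-hand sides.

A :class:`ModelDocument` is the versioned, machine-countable declaration of one
ODE model component: species (with initial values and boundary flags),
parameters (with bounds, units and provenance notes), external inputs, and
processes.  A process is either a ``reaction`` (reactants/products/modifiers
plus a kinetic-law expression) or a ``rate_rule`` (a full ODE right-hand side
for one species).  Rate laws are stored as plain expression strings in the
YAML file; they are parsed once with sympy and compiled to a fast vectorised
numpy callable.  The same parsed expressions back the slow, term-by-term
symbolic evaluator used as an independent oracle in tests, and the SBML
exporter.

Expression language: python/sympy syntax over declared species, parameter and
input names, plus the helpers

* ``hill_act(x, K, n)``  -> ``x**n / (K**n + x**n)``
* ``hill_inh(x, K, n)``  -> ``K**n / (K**n + x**n)``
* ``pos(x)``             -> ``Max(0, x)``
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import sympy as sp
import yaml

__all__ = [
    "Species",
    "Parameter",
    "Process",
    "ModelDocument",
    "load_model",
    "model_path",
]

_MODEL_DIR = Path(__file__).parent / "models"


def model_path(name: str) -> Path:
    """Path of a model-definition YAML shipped with the package."""
    return _MODEL_DIR / f"{name}.yaml"


@dataclass
class Species:
    name: str
    initial: float = 0.0
    boundary: bool = False
    module: str = "core"
    note: str = ""


@dataclass
class Parameter:
    name: str
    value: float
    lower: float = 0.0
    upper: float = np.inf
    units: str = "dimensionless"
    note: str = ""
    provenance: str = "package-default"


@dataclass
class Process:
    """One reaction or rule.

    For ``kind == "reaction"`` the species balance contribution is
    ``stoich * rate`` for each entry of ``reactants`` (negative) and
    ``products`` (positive).  For ``kind == "rate_rule"`` the expression is
    the full time derivative of ``target``.
    """

    id: str
    kind: str  # "reaction" | "rate_rule"
    rate: str
    reactants: dict[str, float] = field(default_factory=dict)
    products: dict[str, float] = field(default_factory=dict)
    modifiers: list[str] = field(default_factory=list)
    target: str = ""
    module: str = "core"
    note: str = ""
    reversible: bool = True


def _expr_locals(symbols: Mapping[str, sp.Symbol]) -> dict:
    x, K, n = sp.symbols("x K n", positive=True)
    loc = dict(symbols)
    loc["hill_act"] = sp.Lambda((x, K, n), x**n / (K**n + x**n))
    loc["hill_inh"] = sp.Lambda((x, K, n), K**n / (K**n + x**n))
    loc["pos"] = sp.Lambda((x,), sp.Max(0, x))
    loc["exp"] = sp.exp
    return loc


class ModelDocument:
    """A declared ODE model component; see module docstring."""

    def __init__(
        self,
        name: str,
        species: Sequence[Species],
        parameters: Sequence[Parameter],
        processes: Sequence[Process],
        inputs: Sequence[str] = (),
        notes: str = "",
    ):
        self.name = name
        self.species = list(species)
        self.parameters = list(parameters)
        self.processes = list(processes)
        self.inputs = list(inputs)
        self.notes = notes
        self._validate()
        self._expr_cache: dict | None = None

    # -- bookkeeping ---------------------------------------------------

    @property
    def species_names(self) -> list[str]:
        return [s.name for s in self.species]

    @property
    def dynamic_species(self) -> list[str]:
        return [s.name for s in self.species if not s.boundary]

    @property
    def parameter_names(self) -> list[str]:
        return [p.name for p in self.parameters]

    def species_index(self, name: str) -> int:
        return self.dynamic_species.index(name)

    def param_value(self, name: str) -> float:
        return next(p.value for p in self.parameters if p.name == name)

    def param_vector(self, overrides: Mapping[str, float] | None = None) -> np.ndarray:
        vals = {p.name: p.value for p in self.parameters}
        if overrides:
            unknown = set(overrides) - set(vals)
            if unknown:
                raise KeyError(f"unknown parameters: {sorted(unknown)}")
            vals.update(overrides)
        return np.array([vals[p.name] for p in self.parameters], float)

    def initial_state(self) -> np.ndarray:
        return np.array([s.initial for s in self.species if not s.boundary], float)

    def counts(self) -> dict[str, int]:
        """Machine-counted structural summary (species / reactions+rules)."""
        return {
            "species": len(self.species),
            "reactions_and_rules": len(self.processes),
            "reactions": sum(p.kind == "reaction" for p in self.processes),
            "rules": sum(p.kind == "rate_rule" for p in self.processes),
        }

    def module_counts(self, module: str) -> dict[str, int]:
        return {
            "species": sum(s.module == module for s in self.species),
            "reactions_and_rules": sum(p.module == module for p in self.processes),
        }

    def _validate(self) -> None:
        names = set(self.species_names)
        if len(names) != len(self.species):
            raise ValueError("duplicate species names")
        pnames = set(self.parameter_names) | set(self.inputs)
        ruled: set[str] = set()
        for pr in self.processes:
            if pr.kind not in ("reaction", "rate_rule"):
                raise ValueError(f"{pr.id}: unknown kind {pr.kind!r}")
            if pr.kind == "rate_rule":
                if pr.target not in names:
                    raise ValueError(f"{pr.id}: rule target {pr.target!r} undeclared")
                if pr.target in ruled:
                    raise ValueError(f"{pr.id}: duplicate rule for {pr.target!r}")
                ruled.add(pr.target)
            for sn in (*pr.reactants, *pr.products, *pr.modifiers):
                if sn not in names:
                    raise ValueError(f"{pr.id}: species {sn!r} undeclared")
        # every rate-law identifier must be a declared species, parameter or input
        symtab = self._symbols()
        loc = _expr_locals(symtab)
        for pr in self.processes:
            expr = sp.sympify(pr.rate, locals=loc)
            free = {str(s) for s in expr.free_symbols}
            undeclared = free - names - pnames
            if undeclared:
                raise ValueError(f"{pr.id}: undeclared identifiers {sorted(undeclared)}")

    # -- symbolic layer ------------------------------------------------

    def _symbols(self) -> dict[str, sp.Symbol]:
        out = {s.name: sp.Symbol(s.name) for s in self.species}
        for p in self.parameters:
            out[p.name] = sp.Symbol(p.name)
        for u in self.inputs:
            out[u] = sp.Symbol(u)
        return out

    def _exprs(self) -> dict:
        """Parsed process rates and assembled per-species derivatives."""
        if self._expr_cache is not None:
            return self._expr_cache
        symtab = self._symbols()
        loc = _expr_locals(symtab)
        rates = {pr.id: sp.sympify(pr.rate, locals=loc) for pr in self.processes}
        deriv: dict[str, sp.Expr] = {n: sp.S.Zero for n in self.dynamic_species}
        for pr in self.processes:
            r = rates[pr.id]
            if pr.kind == "rate_rule":
                if pr.target in deriv:
                    deriv[pr.target] = deriv[pr.target] + r
            else:
                for sn, st in pr.reactants.items():
                    if sn in deriv:
                        deriv[sn] = deriv[sn] - st * r
                for sn, st in pr.products.items():
                    if sn in deriv:
                        deriv[sn] = deriv[sn] + st * r
        self._expr_cache = {"symtab": symtab, "rates": rates, "deriv": deriv}
        return self._expr_cache

    def process_rate_exprs(self) -> dict[str, sp.Expr]:
        return dict(self._exprs()["rates"])

    def derivative_exprs(self) -> dict[str, sp.Expr]:
        return dict(self._exprs()["deriv"])

    def evaluate_processes(
        self,
        state: Mapping[str, float],
        inputs: Mapping[str, float] | None = None,
        params: Mapping[str, float] | None = None,
    ) -> dict[str, float]:
        """Slow, substitution-based evaluation of every process rate.

        Independent of the compiled fast path; used as the term-by-term
        oracle in tests.
        """
        subs = self._full_subs(state, inputs, params)
        return {pid: float(e.xreplace(subs)) for pid, e in self._exprs()["rates"].items()}

    def evaluate_derivatives(
        self,
        state: Mapping[str, float],
        inputs: Mapping[str, float] | None = None,
        params: Mapping[str, float] | None = None,
    ) -> dict[str, float]:
        subs = self._full_subs(state, inputs, params)
        return {n: float(e.xreplace(subs)) for n, e in self._exprs()["deriv"].items()}

    def _full_subs(self, state, inputs, params) -> dict:
        symtab = self._exprs()["symtab"]
        vals: dict[str, float] = {s.name: s.initial for s in self.species if s.boundary}
        vals.update({p.name: p.value for p in self.parameters})
        vals.update({u: 0.0 for u in self.inputs})
        vals.update(state or {})
        vals.update(inputs or {})
        vals.update(params or {})
        return {symtab[k]: sp.Float(v) for k, v in vals.items() if k in symtab}

    def compile_rhs(self) -> Callable[[np.ndarray, np.ndarray, np.ndarray], np.ndarray]:
        """Compile ``f(y, u, p) -> dy/dt`` with numpy broadcasting.

        ``y`` has shape ``(n_dynamic,)`` or ``(n_dynamic, m)`` for a batch of
        ``m`` instances sharing inputs ``u`` and parameters ``p``.  Boundary
        species enter as constants taken from their declared initial values.
        The generated function is JIT-compiled with numba when available.
        """
        if getattr(self, "_rhs_compiled", None) is not None:
            return self._rhs_compiled
        cache = self._exprs()
        symtab = cache["symtab"]
        yv, uv, pv = sp.DeferredVector("y"), sp.DeferredVector("u"), sp.DeferredVector("p")
        subs = {}
        for i, n in enumerate(self.dynamic_species):
            subs[symtab[n]] = yv[i]
        for s in self.species:
            if s.boundary:
                subs[symtab[s.name]] = sp.Float(s.initial)
        for i, n in enumerate(self.inputs):
            subs[symtab[n]] = uv[i]
        for i, p in enumerate(self.parameters):
            subs[symtab[p.name]] = pv[i]
        exprs = [cache["deriv"][n].xreplace(subs) for n in self.dynamic_species]
        f = sp.lambdify(
            (yv, uv, pv),
            exprs,
            modules=[{"Max": np.maximum, "Min": np.minimum}, "numpy"],
            cse=True,
        )
        f = _maybe_jit(f, len(self.dynamic_species))

        def rhs(y: np.ndarray, u: np.ndarray, p: np.ndarray) -> np.ndarray:
            out = f(y, u, p)
            if y.ndim == 1:
                return np.asarray(out, float)
            res = np.empty((len(out), y.shape[1]), float)
            for i, v in enumerate(out):
                res[i] = v
            return res

        self._rhs_compiled = rhs
        return rhs

    # -- persistence ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "notes": self.notes,
            "inputs": list(self.inputs),
            "species": [
                {
                    "name": s.name,
                    "initial": float(s.initial),
                    "boundary": bool(s.boundary),
                    "module": s.module,
                    "note": s.note,
                }
                for s in self.species
            ],
            "parameters": [
                {
                    "name": p.name,
                    "value": float(p.value),
                    "lower": float(p.lower),
                    "upper": None if np.isinf(p.upper) else float(p.upper),
                    "units": p.units,
                    "note": p.note,
                    "provenance": p.provenance,
                }
                for p in self.parameters
            ],
            "processes": [
                {
                    "id": pr.id,
                    "kind": pr.kind,
                    "rate": pr.rate,
                    "reactants": dict(pr.reactants),
                    "products": dict(pr.products),
                    "modifiers": list(pr.modifiers),
                    "target": pr.target,
                    "module": pr.module,
                    "note": pr.note,
                }
                for pr in self.processes
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelDocument":
        species = [
            Species(
                name=s["name"],
                initial=float(s.get("initial", 0.0)),
                boundary=bool(s.get("boundary", False)),
                module=s.get("module", "core"),
                note=s.get("note", ""),
            )
            for s in d["species"]
        ]
        params = [
            Parameter(
                name=p["name"],
                value=float(p["value"]),
                lower=float(p.get("lower", 0.0)),
                upper=np.inf if p.get("upper") is None else float(p["upper"]),
                units=p.get("units", "dimensionless"),
                note=p.get("note", ""),
                provenance=p.get("provenance", "package-default"),
            )
            for p in d["parameters"]
        ]
        procs = [
            Process(
                id=pr["id"],
                kind=pr["kind"],
                rate=pr["rate"],
                reactants={k: float(v) for k, v in (pr.get("reactants") or {}).items()},
                products={k: float(v) for k, v in (pr.get("products") or {}).items()},
                modifiers=list(pr.get("modifiers") or []),
                target=pr.get("target", ""),
                module=pr.get("module", "core"),
                note=pr.get("note", ""),
            )
            for pr in d["processes"]
        ]
        return cls(
            name=d["name"],
            species=species,
            parameters=params,
            processes=procs,
            inputs=list(d.get("inputs") or []),
            notes=d.get("notes", ""),
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ModelDocument":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _maybe_jit(f, n_out: int):
    """JIT the lambdified kernel with numba when possible.

    The generated kernel is pure array arithmetic over its three array
    arguments, so nopython compilation usually succeeds; on any failure the
    plain numpy version is kept.
    """
    try:
        import numba

        jf = numba.njit(cache=False)(f)
        y = np.full(n_out, 0.1)
        probe_u = np.zeros(64)
        probe_p = np.full(1024, 0.5)
        jf(y, probe_u, probe_p)  # force 1-D compilation
        jf(np.tile(y[:, None], (1, 2)), probe_u, probe_p)  # 2-D batch
        return jf
    except Exception:
        return f


from functools import lru_cache as _lru_cache


@_lru_cache(maxsize=None)
def load_model(name: str) -> ModelDocument:
    """Load a packaged model definition (``"macrophage_cell"`` or ``"tissue"``).

    Cached: repeated loads share one parsed (and compiled) document.
    """
    return ModelDocument.from_yaml(model_path(name))
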