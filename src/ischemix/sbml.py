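"""SBML Level 3 export/import for model definitions.

Covers the construct subset used by the packaged models: one compartment,
species (with boundary-condition flags), parameters, reactions with
reactant/product stoichiometries, modifiers and kinetic-law MathML, and rate
rules.  Rate laws are serialized as content MathML produced by a small
dedicated printer (plus the mirroring parser), so an export/import round
trip reproduces the original expressions exactly.  Constructs outside this
subset (events, function definitions, algebraic or assignment rules, ...)
are rejected by the importer with an explicit message naming them — nothing
is silently dropped.

External inputs of the document (the macrophage secretion summaries, ligand
concentrations) are exported as non-constant parameters listed in a small
model annotation so the importer can restore their role.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from pathlib import Path

import sympy as sp

from .modeldef import ModelDocument, Parameter, Process, Species, _expr_locals

__all__ = ["export_sbml", "import_sbml", "write_sbml", "read_sbml"]

SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"
ANN_NS = "urn:ischemix:model-annotations"

_OPMAP = {"plus": sp.Add, "times": sp.Mul}


def _q(tag: str, ns: str = SBML_NS) -> str:
    return f"{{{ns}}}{tag}"


# ----------------------------------------------------------------------
# MathML printing / parsing
# ----------------------------------------------------------------------

def expr_to_mathml(expr: sp.Expr) -> ET.Element:
    math = ET.Element(_q("math", MATHML_NS))
    math.append(_print(expr))
    return math


def _print(e: sp.Expr) -> ET.Element:
    def apply(op: str, *args: sp.Expr) -> ET.Element:
        el = ET.Element(_q("apply", MATHML_NS))
        el.append(ET.Element(_q(op, MATHML_NS)))
        for a in args:
            el.append(_print(a))
        return el

    if isinstance(e, sp.Symbol):
        ci = ET.Element(_q("ci", MATHML_NS))
        ci.text = f" {e.name} "
        return ci
    if isinstance(e, (sp.Integer, sp.Float)) or e.is_number:
        if e == sp.oo or e == -sp.oo:
            raise ValueError("cannot serialize infinite constant to SBML MathML")
        if isinstance(e, sp.Rational) and not isinstance(e, sp.Integer):
            return apply("divide", sp.Integer(e.p), sp.Integer(e.q))
        cn = ET.Element(_q("cn", MATHML_NS))
        if isinstance(e, sp.Integer):
            cn.set("type", "integer")
            cn.text = f" {int(e)} "
        else:
            cn.text = f" {float(e)!r} "
        return cn
    if isinstance(e, sp.Add):
        return apply("plus", *e.args)
    if isinstance(e, sp.Mul):
        return apply("times", *e.args)
    if isinstance(e, sp.Pow):
        return apply("power", e.base, e.exp)
    if isinstance(e, sp.Max):
        return apply("max", *e.args)
    if isinstance(e, sp.Min):
        return apply("min", *e.args)
    if isinstance(e, sp.exp):
        return apply("exp", e.args[0])
    raise ValueError(f"cannot map expression node {type(e).__name__} to SBML MathML")


def mathml_to_expr(math: ET.Element) -> sp.Expr:
    kids = list(math)
    if len(kids) != 1:
        raise ValueError("math element must contain exactly one expression")
    return _parse(kids[0])


def _parse(el: ET.Element) -> sp.Expr:
    tag = el.tag.split("}")[-1]
    if tag == "ci":
        return sp.Symbol(el.text.strip())
    if tag == "cn":
        text = el.text.strip()
        if el.get("type") == "integer":
            return sp.Integer(int(text))
        return sp.Float(text)
    if tag == "apply":
        kids = list(el)
        op = kids[0].tag.split("}")[-1]
        args = [_parse(k) for k in kids[1:]]
        if op == "plus":
            return sp.Add(*args)
        if op == "times":
            return sp.Mul(*args)
        if op == "minus":
            if len(args) == 1:
                return -args[0]
            return args[0] - args[1]
        if op == "divide":
            return args[0] / args[1]
        if op == "power":
            return sp.Pow(args[0], args[1])
        if op == "max":
            return sp.Max(*args)
        if op == "min":
            return sp.Min(*args)
        if op == "exp":
            return sp.exp(args[0])
        raise ValueError(f"unsupported MathML operator <{op}>")
    raise ValueError(f"unsupported MathML element <{tag}>")


# ----------------------------------------------------------------------
# export
# ----------------------------------------------------------------------

def export_sbml(doc: ModelDocument) -> ET.ElementTree:
    """Render a :class:`ModelDocument` as an SBML L3 document."""
    ET.register_namespace("", SBML_NS)
    ET.register_namespace("math", MATHML_NS)
    sbml = ET.Element(_q("sbml"), {"level": "3", "version": "2"})
    model = ET.SubElement(sbml, _q("model"), {"id": doc.name})
    if doc.inputs or doc.notes:
        ann = ET.SubElement(model, _q("annotation"))
        meta = ET.SubElement(ann, f"{{{ANN_NS}}}meta")
        meta.set("inputs", " ".join(doc.inputs))
        if doc.notes:
            meta.set("notes", doc.notes)
    comps = ET.SubElement(model, _q("listOfCompartments"))
    ET.SubElement(comps, _q("compartment"),
                  {"id": "tissue", "constant": "true", "size": "1",
                   "spatialDimensions": "3"})
    if doc.species:
        lspec = ET.SubElement(model, _q("listOfSpecies"))
        for s in doc.species:
            ET.SubElement(lspec, _q("species"), {
                "id": s.name,
                "compartment": "tissue",
                "initialConcentration": repr(float(s.initial)),
                "boundaryCondition": "true" if s.boundary else "false",
                "constant": "false",
                "hasOnlySubstanceUnits": "false",
            })
    if doc.parameters or doc.inputs:
        lpar = ET.SubElement(model, _q("listOfParameters"))
        for p in doc.parameters:
            ET.SubElement(lpar, _q("parameter"), {
                "id": p.name, "value": repr(float(p.value)), "constant": "true"})
        for u in doc.inputs:
            ET.SubElement(lpar, _q("parameter"),
                          {"id": u, "value": "0.0", "constant": "false"})

    symtab = {n: sp.Symbol(n) for n in
              (*doc.species_names, *doc.parameter_names, *doc.inputs)}
    loc = _expr_locals(symtab)

    rules = [pr for pr in doc.processes if pr.kind == "rate_rule"]
    reactions = [pr for pr in doc.processes if pr.kind == "reaction"]
    if rules:
        lrules = ET.SubElement(model, _q("listOfRules"))
        for pr in rules:
            r = ET.SubElement(lrules, _q("rateRule"), {"variable": pr.target})
            r.append(expr_to_mathml(sp.sympify(pr.rate, locals=loc)))
    if reactions:
        lrx = ET.SubElement(model, _q("listOfReactions"))
        for pr in reactions:
            rx = ET.SubElement(lrx, _q("reaction"),
                               {"id": pr.id, "reversible": "true"})
            if pr.reactants:
                lr = ET.SubElement(rx, _q("listOfReactants"))
                for sn, st in pr.reactants.items():
                    ET.SubElement(lr, _q("speciesReference"),
                                  {"species": sn, "stoichiometry": repr(float(st)),
                                   "constant": "true"})
            if pr.products:
                lp = ET.SubElement(rx, _q("listOfProducts"))
                for sn, st in pr.products.items():
                    ET.SubElement(lp, _q("speciesReference"),
                                  {"species": sn, "stoichiometry": repr(float(st)),
                                   "constant": "true"})
            if pr.modifiers:
                lm = ET.SubElement(rx, _q("listOfModifiers"))
                for sn in pr.modifiers:
                    ET.SubElement(lm, _q("modifierSpeciesReference"), {"species": sn})
            kl = ET.SubElement(rx, _q("kineticLaw"))
            kl.append(expr_to_mathml(sp.sympify(pr.rate, locals=loc)))
    return ET.ElementTree(sbml)


def write_sbml(doc: ModelDocument, path: str | Path) -> Path:
    path = Path(path)
    tree = export_sbml(doc)
    ET.indent(tree)
    tree.write(path, xml_declaration=True, encoding="unicode")
    return path


# ----------------------------------------------------------------------
# import
# ----------------------------------------------------------------------

_UNSUPPORTED = ["listOfEvents", "listOfFunctionDefinitions", "listOfConstraints",
                "listOfInitialAssignments", "algebraicRule", "assignmentRule"]


def import_sbml(tree: ET.ElementTree | ET.Element) -> ModelDocument:
    """Rebuild a :class:`ModelDocument` from an SBML L3 document.

    Inverse of :func:`export_sbml` on the supported construct subset;
    unsupported SBML features raise with their names listed.
    """
    root = tree.getroot() if isinstance(tree, ET.ElementTree) else tree
    model = root.find(_q("model"))
    if model is None:
        raise ValueError("no <model> element found")
    bad = sorted({el.tag.split('}')[-1] for el in model.iter()
                  if el.tag.split('}')[-1] in _UNSUPPORTED})
    if bad:
        raise ValueError(f"unsupported SBML features: {', '.join(bad)}")

    inputs: list[str] = []
    notes = ""
    ann = model.find(_q("annotation"))
    if ann is not None:
        meta = ann.find(f"{{{ANN_NS}}}meta")
        if meta is not None:
            inputs = (meta.get("inputs") or "").split()
            notes = meta.get("notes", "")

    species = []
    for s in model.iter(_q("species")):
        species.append(Species(
            name=s.get("id"),
            initial=float(s.get("initialConcentration", 0.0)),
            boundary=s.get("boundaryCondition") == "true",
        ))
    params = []
    for p in model.iter(_q("parameter")):
        if p.get("id") in inputs:
            continue
        params.append(Parameter(name=p.get("id"), value=float(p.get("value")),
                                lower=0.0, upper=float("inf"),
                                provenance="sbml-import"))

    processes = []
    for r in model.iter(_q("rateRule")):
        math = r.find(_q("math", MATHML_NS))
        processes.append(Process(
            id=f"rule_{r.get('variable').lower()}", kind="rate_rule",
            target=r.get("variable"), rate=str(mathml_to_expr(math))))
    for rx in model.iter(_q("reaction")):
        def refs(tag: str) -> dict[str, float]:
            lst = rx.find(_q(tag))
            if lst is None:
                return {}
            return {e.get("species"): float(e.get("stoichiometry", 1.0))
                    for e in lst}
        lm = rx.find(_q("listOfModifiers"))
        mods = [e.get("species") for e in lm] if lm is not None else []
        kl = rx.find(_q("kineticLaw"))
        math = kl.find(_q("math", MATHML_NS))
        processes.append(Process(
            id=rx.get("id"), kind="reaction",
            reactants=refs("listOfReactants"), products=refs("listOfProducts"),
            modifiers=mods, rate=str(mathml_to_expr(math))))
    return ModelDocument(name=model.get("id", "imported"), species=species,
                         parameters=params, processes=processes, inputs=inputs,
                         notes=notes)


def read_sbml(path: str | Path) -> ModelDocument:
    return import_sbml(ET.parse(path))
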