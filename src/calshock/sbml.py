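"""Optional cross-check against a deposited SBML encoding of the model.

The published model is archived in the BioModels repository (accession
MODEL2112030001, SBML Level 2 Version 5).  When a local copy of that file
and the ``python-libsbml`` package are both available, the initial species
concentrations and parameter values can be extracted and compared with this
package's defaults.  Nothing in the package requires this: it is a
convenience for users who want an independent consistency check.
"""

from __future__ import annotations

from pathlib import Path

__all__ = ["load_sbml_values"]


def load_sbml_values(path: str | Path) -> dict:
    """Initial concentrations and parameter values from an SBML file.

    Returns ``{"species": {id: initial}, "parameters": {id: value},
    "compartments": {id: size}}``.  Requires ``python-libsbml``.
    """
    try:
        import libsbml
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "python-libsbml is required for the SBML cross-check; "
            "install the 'sbml' extra"
        ) from exc

    doc = libsbml.readSBMLFromString(Path(path).read_text())
    if doc.getNumErrors() and doc.getError(0).getSeverity() >= libsbml.LIBSBML_SEV_ERROR:
        raise ValueError(f"{path}: {doc.getError(0).getMessage()}")
    model = doc.getModel()
    if model is None:
        raise ValueError(f"{path}: no model element")
    species = {}
    for i in range(model.getNumSpecies()):
        s = model.getSpecies(i)
        species[s.getId()] = (
            s.getInitialConcentration()
            if s.isSetInitialConcentration()
            else s.getInitialAmount()
        )
    parameters = {
        model.getParameter(i).getId(): model.getParameter(i).getValue()
        for i in range(model.getNumParameters())
    }
    compartments = {
        model.getCompartment(i).getId(): model.getCompartment(i).getSize()
        for i in range(model.getNumCompartments())
    }
    return {"species": species, "parameters": parameters,
            "compartments": compartments}
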