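"""Accessors for the gene-set libraries shipped with the package.

All of these are defaults, overridable with a user GMT at every call site:

* ``cell_cycle`` — canonical 43-gene G1/S and 54-gene G2/M phase programs.
* ``marker_panels`` — the cell-typing panels: T (CD2, CD3D, CD3E, CD3G),
  B (CD19, MS4A1, CD79A, CD79B), monocyte (CD14, CD68, CD163),
  leukocyte (PTPRC), lung origin (SFTPA1, SFTPA2, SFTPB, NAPSA),
  epithelial (EPCAM, CDH1, KRT7, KRT8, KRT18, MUC1), proliferation
  (CCND1, TOP2A).
* ``emt_sets`` — epithelial7 / mes_csc / ecm sets used for the partial-EMT
  and ECM state scores.
* ``immune_signature`` — curated 60-gene canonical immune marker list used by
  the single-sample immune score.
* ``cta_synthetic`` — a constructed stand-in list of 276 cancer-testis
  antigen family symbols (the reference CT database list is not
  redistributable here); users should substitute their own list for real
  analyses.
"""

from importlib import resources

from .io import GeneSetLibrary, load_gmt

_FILES = {
    "cell_cycle": "cell_cycle.gmt",
    "marker_panels": "marker_panels.gmt",
    "emt_sets": "emt_sets.gmt",
    "immune_signature": "immune_signature.gmt",
    "cta_synthetic": "cta_synthetic.gmt",
}


def load_bundled(name: str) -> GeneSetLibrary:
    if name not in _FILES:
        raise KeyError(f"unknown bundled library {name!r}; choose from {sorted(_FILES)}")
    ref = resources.files("csfctc.data") / _FILES[name]
    with resources.as_file(ref) as path:
        return load_gmt(path)


def cell_cycle_sets() -> tuple[list[str], list[str]]:
    """Return the (G1/S, G2/M) default gene lists."""
    lib = load_bundled("cell_cycle")
    return lib["G1S"], lib["G2M"]


def marker_panels() -> GeneSetLibrary:
    return load_bundled("marker_panels")


def emt_sets() -> GeneSetLibrary:
    return load_bundled("emt_sets")


def immune_signature() -> list[str]:
    return load_bundled("immune_signature")["immune_signature"]


def cta_list() -> list[str]:
    """The bundled synthetic stand-in CTA list (276 symbols)."""
    return load_bundled("cta_synthetic")["cta_276"]
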