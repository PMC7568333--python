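"""Synthetic demonstration topology for the pteropod study system.

``pteropod_demo_tree`` returns a hand-built 28-taxon chronogram (25 pteropods
plus 3 heterobranch outgroups) whose clade structure mirrors the study
system: Pteropoda splits into Thecosomata (Euthecosomata = Cavolinioidea +
Limacinoidea, plus Pseudothecosomata) and Gymnosomata.  The topology and its
node ages are a synthetic stand-in assembled for demonstrations and tests —
they are not an estimate — but every named clade needed by the fossil
calibration tables resolves on it.
"""

from __future__ import annotations

from .formats import DatedTree, read_newick_dated

OUTGROUPS = ["Aplysia_californica", "Haminoea_antillarum", "Philine_angasi"]

CAVOLINIOIDEA = [
    "Diacria_trispinosa", "Diacria_quadridentata",
    "Cavolinia_uncinata", "Diacavolinia_longirostris",
    "Clio_pyramidata", "Clio_cuspidata",
    "Creseis_acicula", "Creseis_virgula", "Styliola_subula", "Hyalocylis_striata",
]
LIMACINOIDEA = [
    "Limacina_helicina", "Limacina_bulimoides", "Limacina_retroversa",
    "Limacina_trochiformis", "Heliconoides_inflatus", "Thielea_helicoides",
]
PSEUDOTHECOSOMATA = [
    "Peracle_reticulata", "Peracle_bispinosa", "Corolla_ovata",
    "Cymbulia_sibogae", "Desmopterus_papilio",
]
GYMNOSOMATA = [
    "Clione_limacina", "Pneumoderma_violaceum", "Paraclione_longicaudata",
    "Cliopsis_krohni",
]

INGROUP = CAVOLINIOIDEA + LIMACINOIDEA + PSEUDOTHECOSOMATA + GYMNOSOMATA


def clade_definitions() -> dict[str, set]:
    """Named clades used by the fossil calibration tables."""
    return {
        "Diacria": {"Diacria_trispinosa", "Diacria_quadridentata"},
        "Cavolinia+Diacavolinia": {
            "Cavolinia_uncinata", "Diacavolinia_longirostris"
        },
        "Cavolinia+Diacavolinia+Diacria": {
            "Diacria_trispinosa", "Diacria_quadridentata",
            "Cavolinia_uncinata", "Diacavolinia_longirostris",
        },
        "Cavolinioidea": set(CAVOLINIOIDEA),
        "Limacina": {
            "Limacina_helicina", "Limacina_bulimoides", "Limacina_retroversa",
            "Limacina_trochiformis",
        },
        "Limacinoidea": set(LIMACINOIDEA),
        "Euthecosomata": set(CAVOLINIOIDEA) | set(LIMACINOIDEA),
        "Pseudothecosomata": set(PSEUDOTHECOSOMATA),
        "Gymnosomata": set(GYMNOSOMATA),
        "Thecosomata": set(CAVOLINIOIDEA) | set(LIMACINOIDEA) | set(PSEUDOTHECOSOMATA),
        "Pteropoda": set(INGROUP),
    }


def pteropod_demo_tree() -> tuple[DatedTree, dict[str, set]]:
    """The demo chronogram and its clade definitions.

    Crown ages of the template: Pteropoda 130, Thecosomata 115, Euthecosomata
    100, Cavolinioidea 70, Limacinoidea 85, Pseudothecosomata 85, Gymnosomata
    75, root (all 28 taxa) 154 Ma.
    """
    nwk = (
        "((((" + _cav() + "," + _lim() + "):15," + _pse() + "):15," + _gym()
        + "):24," + _out() + ");"
    )
    tree = read_newick_dated(nwk)
    return tree, clade_definitions()


def _cav() -> str:
    return (
        "(((Diacria_trispinosa:20,Diacria_quadridentata:20):25,"
        "((Cavolinia_uncinata:18,Diacavolinia_longirostris:18):12,"
        "(Clio_pyramidata:14,Clio_cuspidata:14):16):15):25,"
        "((Creseis_acicula:22,Creseis_virgula:22):28,"
        "(Styliola_subula:30,Hyalocylis_striata:30):20):20):30"
    )


def _lim() -> str:
    return (
        "((((Limacina_helicina:25,Limacina_trochiformis:25):15,"
        "(Limacina_bulimoides:22,Limacina_retroversa:22):18):25,"
        "Heliconoides_inflatus:65):20,Thielea_helicoides:85):15"
    )


def _pse() -> str:
    return (
        "(((Peracle_reticulata:30,Peracle_bispinosa:30):30,"
        "(Corolla_ovata:35,Cymbulia_sibogae:35):25):25,"
        "Desmopterus_papilio:85):30"
    )


def _gym() -> str:
    return (
        "((Clione_limacina:40,Paraclione_longicaudata:40):35,"
        "(Pneumoderma_violaceum:55,Cliopsis_krohni:55):20):55"
    )


def _out() -> str:
    return "((Haminoea_antillarum:120,Philine_angasi:120):20,Aplysia_californica:140):14"
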