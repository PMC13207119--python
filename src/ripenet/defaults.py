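"""Shipped default catalogs: mutant panel, feature catalog, pathway map, presets.

The defaults emulate a five-mutant tomato ripening panel: loss-of-function
mutants *at* (IDI1), *r* (PSY1) and *t* (CrtISO1) plus gain-of-function branch
mutants *B* (CYC-b, beta-beta branch) and *Del* (LCY-e, epsilon-beta branch),
matched against two wild-type backgrounds (AC for at/r/t/B, M82 for Del),
sampled at the MG, Br and FR ripening stages.  The allele-strength parameters
(leakiness, gain, backlog) are illustrative defaults, not measured values.
"""

from __future__ import annotations

from .core_model import (
    DesignMap,
    FeatureDescriptor,
    PathwayEdge,
    PathwayMap,
    SampleDescriptor,
)

WILDTYPES = ("AC", "M82")
MUTANT_ORDER = ("at", "r", "t", "B", "Del")
STAGE_ORDER = ("MG", "Br", "FR")


def default_design_map() -> DesignMap:
    return DesignMap(
        mutant_to_wildtype={"at": "AC", "r": "AC", "t": "AC", "B": "AC", "Del": "M82"}
    )


def default_samples(n_replicates: int = 3) -> list[SampleDescriptor]:
    """Full panel: 7 genotypes x 3 stages x n replicates."""
    design = default_design_map()
    samples = []
    for g in (*WILDTYPES, *MUTANT_ORDER):
        background = g if g in WILDTYPES else design.wildtype_of(g)
        for stage in STAGE_ORDER:
            for rep in range(1, n_replicates + 1):
                samples.append(
                    SampleDescriptor(
                        sample_id=f"{g}_{stage}_{rep}",
                        genotype=g,
                        background=background,
                        stage=stage,
                        replicate=rep,
                    )
                )
    return samples


def _m(fid, name, cls, branch=None, step=None):
    return FeatureDescriptor(fid, name, "metabolite", cls, branch, step)


def _t(fid, name, cls):
    return FeatureDescriptor(fid, name, "transcript", cls)


def default_feature_catalog() -> list[FeatureDescriptor]:
    """Metabolite + transcript catalog of the default panel.

    Pathway-positioned carotenoids carry a (branch_id, step_index) address used
    for export ordering; cis-isomers and panel compounds (ABA, chlorophylls,
    tocochromanols, quinones, precursor intermediates) are catalogued without a
    pathway position.
    """
    metabolites = [
        # core linear pathway (branch "core")
        _m("IPP", "isopentenyl diphosphate", "MEP", "core", 0),
        _m("GGPP", "geranylgeranyl diphosphate", "MEP", "core", 1),
        _m("phytoene", "15-cis-phytoene", "CAR", "core", 2),
        _m("phytofluene", "phytofluene", "CAR", "core", 3),
        _m("zeta_carotene", "zeta-carotene", "CAR", "core", 4),
        _m("neurosporene", "neurosporene", "CAR", "core", 5),
        _m("prolycopene", "prolycopene (7,9,7',9'-tetra-cis-lycopene)", "CAR", "core", 6),
        _m("lycopene", "all-trans-lycopene", "CAR", "core", 7),
        # epsilon-beta branch
        _m("delta_carotene", "delta-carotene", "CAR", "epsilon", 0),
        _m("alpha_carotene", "alpha-carotene", "CAR", "epsilon", 1),
        _m("lutein", "lutein", "CAR", "epsilon", 2),
        # beta-beta branch
        _m("gamma_carotene", "gamma-carotene", "CAR", "beta", 0),
        _m("beta_carotene", "beta-carotene", "CAR", "beta", 1),
        _m("beta_cryptoxanthin", "beta-cryptoxanthin", "CAR", "beta", 2),
        _m("zeaxanthin", "zeaxanthin", "CAR", "beta", 3),
        _m("antheraxanthin", "antheraxanthin", "CAR", "beta", 4),
        _m("violaxanthin", "violaxanthin", "CAR", "beta", 5),
        _m("neoxanthin", "neoxanthin", "CAR", "beta", 6),
        # ABA branch off neoxanthin
        _m("xanthoxin", "xanthoxin", "ABA", "aba", 0),
        _m("ABA", "abscisic acid", "ABA", "aba", 1),
        # off-map isomers and related carotenoids
        _m("lycopene_5_cis", "5-cis-lycopene", "CAR"),
        _m("lycopene_9_cis", "9-cis-lycopene", "CAR"),
        _m("lycopene_13_cis", "13-cis-lycopene", "CAR"),
        _m("beta_carotene_9_cis", "9-cis-beta-carotene", "CAR"),
        _m("luteoxanthin", "luteoxanthin", "CAR"),
        _m("lutein_epoxide", "lutein 5,6-epoxide", "CAR"),
        _m("ABA_GE", "ABA glucose ester", "ABA"),
        # precursor-pathway intermediates
        _m("DXP", "1-deoxy-D-xylulose 5-phosphate", "MEP"),
        _m("MEcPP", "2-C-methyl-D-erythritol 2,4-cyclodiphosphate", "MEP"),
        _m("mevalonate", "mevalonate", "MVA"),
        _m("HMG_CoA", "3-hydroxy-3-methylglutaryl-CoA", "MVA"),
        # pigment / tocochromanol / quinone panels
        _m("chlorophyll_a", "chlorophyll a", "CHL"),
        _m("chlorophyll_b", "chlorophyll b", "CHL"),
        _m("alpha_tocopherol", "alpha-tocopherol", "TOC"),
        _m("gamma_tocopherol", "gamma-tocopherol", "TOC"),
        _m("delta_tocopherol", "delta-tocopherol", "TOC"),
        _m("phylloquinone", "phylloquinone (vitamin K1)", "QUI"),
        _m("ubiquinone_9", "ubiquinone-9", "QUI"),
        _m("ubiquinone_10", "ubiquinone-10", "QUI"),
    ]
    transcripts = [
        _t("DXS-1", "1-deoxy-D-xylulose-5-phosphate synthase 1", "MEP"),
        _t("DXS-2", "1-deoxy-D-xylulose-5-phosphate synthase 2", "MEP"),
        _t("DXR", "1-deoxy-D-xylulose-5-phosphate reductoisomerase", "MEP"),
        _t("HDR", "4-hydroxy-3-methylbut-2-enyl diphosphate reductase", "MEP"),
        _t("IDI1", "isopentenyl diphosphate isomerase 1", "MEP"),
        _t("GGPS-2", "geranylgeranyl diphosphate synthase 2", "MEP"),
        _t("AACT-2", "acetoacetyl-CoA thiolase 2", "MVA"),
        _t("HMGR-1", "HMG-CoA reductase 1", "MVA"),
        _t("FPS", "farnesyl diphosphate synthase", "MVA"),
        _t("PSY1", "phytoene synthase 1", "CAR"),
        _t("PSY2", "phytoene synthase 2", "CAR"),
        _t("PSY3", "phytoene synthase 3", "CAR"),
        _t("PDS", "phytoene desaturase", "CAR"),
        _t("PTOX", "plastid terminal oxidase", "CAR"),
        _t("Z-ISO", "zeta-carotene isomerase", "CAR"),
        _t("ZDS", "zeta-carotene desaturase", "CAR"),
        _t("CrtISO1", "carotenoid isomerase 1", "CAR"),
        _t("CrtISO2", "carotenoid isomerase 2", "CAR"),
        _t("LCY-b1", "lycopene beta-cyclase 1", "CAR"),
        _t("LCY-b2", "lycopene beta-cyclase 2", "CAR"),
        _t("LCY-e", "lycopene epsilon-cyclase", "CAR"),
        _t("CYC-b", "chromoplast-specific lycopene beta-cyclase", "CAR"),
        _t("CHY1", "beta-carotene hydroxylase 1", "CAR"),
        _t("CHY2", "beta-carotene hydroxylase 2", "CAR"),
        _t("LUT5", "cytochrome P450 carotene hydroxylase", "CAR"),
        _t("ZEP", "zeaxanthin epoxidase", "CAR"),
        _t("NXS", "neoxanthin synthase", "CAR"),
        _t("NCED", "9-cis-epoxycarotenoid dioxygenase", "ABA"),
        _t("AAO3", "abscisic aldehyde oxidase 3", "ABA"),
        _t("CCD1a", "carotenoid cleavage dioxygenase 1a", "CAR"),
        _t("VTE4", "gamma-tocopherol methyltransferase", "TOC"),
    ]
    return metabolites + transcripts


def default_pathway_map() -> PathwayMap:
    """Carotenoid pathway DAG with the epsilon-beta / beta-beta split at lycopene."""
    edges = [
        PathwayEdge("IPP", "GGPP", "IDI1"),
        PathwayEdge("GGPP", "phytoene", "PSY1"),
        PathwayEdge("phytoene", "phytofluene", "PDS"),
        PathwayEdge("phytofluene", "zeta_carotene", "Z-ISO"),
        PathwayEdge("zeta_carotene", "neurosporene", "ZDS"),
        PathwayEdge("neurosporene", "prolycopene", "ZDS"),
        PathwayEdge("prolycopene", "lycopene", "CrtISO1"),
        PathwayEdge("lycopene", "delta_carotene", "LCY-e"),
        PathwayEdge("lycopene", "gamma_carotene", "CYC-b"),
        PathwayEdge("delta_carotene", "alpha_carotene", "LCY-b1"),
        PathwayEdge("alpha_carotene", "lutein", "LUT5"),
        PathwayEdge("gamma_carotene", "beta_carotene", "CYC-b"),
        PathwayEdge("beta_carotene", "beta_cryptoxanthin", "CHY1"),
        PathwayEdge("beta_cryptoxanthin", "zeaxanthin", "CHY2"),
        PathwayEdge("zeaxanthin", "antheraxanthin", "ZEP"),
        PathwayEdge("antheraxanthin", "violaxanthin", "ZEP"),
        PathwayEdge("violaxanthin", "neoxanthin", "NXS"),
        PathwayEdge("neoxanthin", "xanthoxin", "NCED"),
        PathwayEdge("xanthoxin", "ABA", "AAO3"),
    ]
    nodes: list[str] = []
    for e in edges:
        for n in (e.substrate, e.product):
            if n not in nodes:
                nodes.append(n)
    return PathwayMap(
        nodes=nodes,
        edges=edges,
        branch_fractions={"lycopene": {"delta_carotene": 0.4, "gamma_carotene": 0.6}},
    )


#: causative gene of each mutant (hub of its network)
MUTANT_GENES = {"at": "IDI1", "r": "PSY1", "t": "CrtISO1", "B": "CYC-b", "Del": "LCY-e"}
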