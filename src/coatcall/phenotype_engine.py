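"""Dominance/recessivity/epistasis rules mapping panel genotypes to a coat
and iris phenotype.

The rule table encodes classical cat coat-color genetics as exercised by the
panel: recessive loci (TYR colour-point/albino series, TYRP1 browns, MC1R
amber, MLPH dilution, ASIP nonagouti, LVRN blotched tabby, FGF5 long fur,
KRT71/LPAR6 coat texture, KIT gloves and salmiak) express only from a
homozygous — or established trans compound-heterozygous — genotype; the KIT
endogenous-retrovirus insertions (full white, white spotting) and the PAX3
blue-iris insertions act dominantly; the orange locus is X-linked.

Two epistatic masks are applied, in fixed precedence: full white masks all
base-colour reporting (and spotting outranks the other white patterns), and
the nonagouti genotype suppresses tabby-pattern expression, so blotched or
ticked genotypes are reported as masked rather than expressed.

Compound heterozygosity requires an established trans phase from read
evidence; two unphased heterozygous calls at one gene are conservatively
reported "phase unknown" and do not express (this is exactly the published
LVRN situation in PG-4).  Consequence: adding a single heterozygous call at
any recessive locus can never change a report (carrier invariance).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .genotyper import GenotypeCall
from .panel import PanelLocus, load_panel
from .sv_detector import SVCall

__all__ = ["GenotypeVector", "PhenotypeReport", "infer_phenotype", "explain"]

_PRESENT = {"het", "hom_alt", "present"}


@dataclass
class GenotypeVector:
    """Per-sample map locus_id -> GenotypeCall or SVCall, with optional sex
    and phase evidence (map of locus-id pairs -> cis/trans/unknown)."""

    sample_id: str
    calls: dict[str, GenotypeCall | SVCall] = field(default_factory=dict)
    sex: str = "unknown"
    phase: dict[tuple[str, str], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for lid, call in self.calls.items():
            if call.locus_id != lid:
                raise ValueError(f"contradictory call at locus {lid}: "
                                 f"entry is for {call.locus_id}")
        self.phase = {tuple(sorted(k)): v for k, v in self.phase.items()}

    def zygosity(self, locus_id: str) -> tuple[str, bool]:
        """(state, assumed) with state in hom_ref/het/hom_alt/present/no_call;
        loci absent from the map are hom_ref with the assumed flag set."""
        call = self.calls.get(locus_id)
        if call is None:
            return "hom_ref", True
        if isinstance(call, SVCall):
            state = {"absent": "hom_ref", "het": "het", "hom": "hom_alt",
                     "present": "present"}.get(call.genotype, "no_call")
            return state, False
        if isinstance(call, GenotypeCall):
            return call.call, False
        raise TypeError(f"unsupported call type at {locus_id}")

    def trans_established(self, locus_a: str, locus_b: str) -> bool:
        return self.phase.get(tuple(sorted((locus_a, locus_b)))) == "trans"


@dataclass
class PhenotypeReport:
    sample_id: str
    base_color: str = "black"            # black/chocolate/cinnamon/amber-class/orange/masked
    color_modifier: str = "none"         # colorpoint/albino/burmese/mocha
    dilution: str = "none"
    white_pattern: str = "none"          # spotting_bicolor/full_white/gloves/salmiak
    tabby_pattern: str = "mackerel_default"
    coat_length: str = "short"
    coat_texture: str = "normal"
    iris: str = "non-blue"
    justifications: list[tuple[str, str, str]] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)
    assumed_loci: list[str] = field(default_factory=list)

    def cite(self, trait: str, locus: str, rule: str) -> None:
        self.justifications.append((trait, locus, rule))


def _gene_loci(panel: list[PanelLocus], gene: str) -> list[PanelLocus]:
    return [lo for lo in panel if lo.gene == gene]


def _expressed_recessive(gv: GenotypeVector, loci: list[PanelLocus]
                         ) -> tuple[PanelLocus | None, str, list[str]]:
    """Which allele of a recessive gene is expressed, if any.

    Returns (locus, how, unresolved) — ``how`` is 'hom' or 'compound_trans';
    ``unresolved`` lists het loci that could not be phased into a compound
    genotype.
    """
    homs = [lo for lo in loci if gv.zygosity(lo.locus_id)[0] == "hom_alt"]
    if homs:
        return homs[0], "hom", []
    hets = [lo for lo in loci if gv.zygosity(lo.locus_id)[0] == "het"]
    for i, a in enumerate(hets):
        for b in hets[i + 1:]:
            if gv.trans_established(a.locus_id, b.locus_id):
                return a, "compound_trans", []
    return None, "", [lo.locus_id for lo in hets] if len(hets) >= 2 else []


def infer_phenotype(gv: GenotypeVector,
                    panel: list[PanelLocus] | None = None) -> PhenotypeReport:
    """Apply the rule table to one genotype vector.

    Missing loci are treated as homozygous reference and flagged; every
    non-default trait cites at least one (locus, rule) justification.
    """
    panel = panel if panel is not None else load_panel()
    by_id = {lo.locus_id: lo for lo in panel}
    rep = PhenotypeReport(sample_id=gv.sample_id)
    rep.assumed_loci = sorted(
        lid for lid in by_id if gv.zygosity(lid)[1])

    def state(lid: str) -> str:
        return gv.zygosity(lid)[0]

    # -- 1. white patterns (dominant insertions first, then recessives) ----
    if state("KIT_wW") in _PRESENT:
        rep.white_pattern = "full_white"
        rep.cite("white_pattern", "KIT_wW",
                 "FERV1-LTR insertion in KIT intron 1 is dominant: full white")
    elif state("KIT_wS") in _PRESENT:
        rep.white_pattern = "spotting_bicolor"
        rep.cite("white_pattern", "KIT_wS",
                 "full FERV1 insertion in KIT intron 1 is dominant: white spotting")
    elif state("KIT_wSal") == "hom_alt":
        rep.white_pattern = "salmiak"
        rep.cite("white_pattern", "KIT_wSal",
                 "homozygous 95 kb KIT-KDR deletion: salmiak (recessive, "
                 "inheritance annotation external)")
    elif state("KIT_wg") == "hom_alt":
        rep.white_pattern = "gloves"
        rep.cite("white_pattern", "KIT_wg", "homozygous KIT gloving allele")

    # -- 2. base colour ----------------------------------------------------
    tyr_modifiers = {"TYR_cs": "colorpoint", "TYR_ca": "albino",
                     "TYR_cb": "burmese", "TYR_cm": "mocha"}
    tyr_hit, how, tyr_unresolved = _expressed_recessive(
        gv, _gene_loci(panel, "TYR"))
    if tyr_hit is not None:
        rep.color_modifier = tyr_modifiers.get(tyr_hit.locus_id, "colorpoint")
        rep.cite("color_modifier", tyr_hit.locus_id,
                 f"TYR mutant genotype is recessive; expressed from {how}")
    elif tyr_unresolved:
        rep.notes.append(
            "two heterozygous TYR alleles with phase unknown: compound "
            "heterozygosity not established; full colour assumed")

    tyrp1_hit, how, _ = _expressed_recessive(gv, _gene_loci(panel, "TYRP1"))
    if tyrp1_hit is not None:
        rep.base_color = ("cinnamon" if tyrp1_hit.locus_id == "TYRP1_bl"
                          else "chocolate")
        rep.cite("base_color", tyrp1_hit.locus_id,
                 f"recessive TYRP1 brown allele expressed from {how}")
    if state("MC1R_e") == "hom_alt":
        rep.base_color = "amber-class"
        rep.cite("base_color", "MC1R_e", "homozygous recessive MC1R allele")

    orange = state("ARHGAP36_o")
    if orange in ("het", "hom_alt", "present"):
        if gv.sex == "XY":
            rep.base_color = "orange"
            rep.cite("base_color", "ARHGAP36_o",
                     "X-linked orange deletion hemizygous in a male")
        elif gv.sex == "XX" and orange == "hom_alt":
            rep.base_color = "orange"
            rep.cite("base_color", "ARHGAP36_o",
                     "X-linked orange deletion on both X copies")
        elif gv.sex == "XX":
            rep.notes.append("heterozygous X-linked orange in a female: "
                             "tortoiseshell possible")
        else:
            rep.notes.append(
                "X-linked orange with unknown sex: if XY -> orange; if XX "
                "het -> tortoiseshell possible, hom -> orange")

    if rep.white_pattern == "full_white":
        if rep.base_color != "black" or rep.color_modifier != "none":
            rep.notes.append("base colour genotype masked by full white")
        rep.base_color = "masked"
        rep.cite("base_color", "KIT_wW", "full white masks base colour")

    # -- 3. dilution -------------------------------------------------------
    if state("MLPH_d") == "hom_alt":
        rep.dilution = "dilute"
        rep.cite("dilution", "MLPH_d",
                 "MLPH dilute genotype is recessive; expressed only when homozygous")

    # -- 4. tabby pattern --------------------------------------------------
    lvrn_hit, lvrn_how, lvrn_unresolved = _expressed_recessive(
        gv, _gene_loci(panel, "LVRN"))
    dkk4_hits = [lo for lo in _gene_loci(panel, "DKK4")
                 if state(lo.locus_id) in _PRESENT]
    if state("ASIP_a") == "hom_alt":
        rep.tabby_pattern = "suppressed_solid"
        rep.cite("tabby_pattern", "ASIP_a",
                 "homozygous nonagouti suppresses tabby pattern expression")
        if lvrn_hit is not None:
            rep.cite("tabby_pattern", lvrn_hit.locus_id,
                     "blotched-tabby genotype present but masked by nonagouti")
        for lo in dkk4_hits:
            rep.cite("tabby_pattern", lo.locus_id,
                     "ticked genotype present but masked by nonagouti")
    else:
        if lvrn_hit is not None:
            rep.tabby_pattern = "blotched"
            rep.cite("tabby_pattern", lvrn_hit.locus_id,
                     f"recessive blotched-tabby allele expressed from {lvrn_how}")
        elif dkk4_hits:
            rep.tabby_pattern = "ticked"
            rep.cite("tabby_pattern", dkk4_hits[0].locus_id,
                     "DKK4 ticked allele (dominant; inheritance annotation external)")
    if lvrn_unresolved:
        rep.notes.append(
            "two heterozygous LVRN alleles with phase unknown: compound "
            "heterozygosity not established")

    # -- 5. coat length ----------------------------------------------------
    fgf5_hit, fgf5_how, fgf5_unresolved = _expressed_recessive(
        gv, _gene_loci(panel, "FGF5"))
    if fgf5_hit is not None:
        rep.coat_length = "long"
        rep.cite("coat_length", fgf5_hit.locus_id,
                 "homozygous FGF5 long-fur allele" if fgf5_how == "hom" else
                 "trans compound heterozygote of two FGF5 long-fur alleles")
    if fgf5_unresolved:
        rep.notes.append(
            "two heterozygous FGF5 alleles with phase unknown: compound "
            "heterozygosity not established")

    # -- 6. coat texture ---------------------------------------------------
    if state("KRT71_hr") == "hom_alt":
        rep.coat_texture = "hairless"
        rep.cite("coat_texture", "KRT71_hr", "homozygous KRT71 hairless allele")
    else:
        rex_loci = ["KRT71_re_complex", "KRT71_re_445", "LPAR6_re"]
        rex_hit, rex_how, _ = _expressed_recessive(
            gv, [by_id[lid] for lid in rex_loci])
        if rex_hit is not None:
            rep.coat_texture = "rex"
            rep.cite("coat_texture", rex_hit.locus_id,
                     f"recessive rexing allele expressed from {rex_how}")

    # -- 7. iris -----------------------------------------------------------
    pax3 = [lid for lid in ("PAX3_DBE_Cel", "PAX3_DBE_ALT")
            if state(lid) in _PRESENT]
    if pax3:
        rep.iris = "blue"
        rep.cite("iris", pax3[0],
                 "dominant LTR insertion in PAX3 intron 4: blue iris")
    elif rep.white_pattern == "full_white":
        rep.iris = "blue_or_odd_possible"
        rep.cite("iris", "KIT_wW",
                 "full white: blue or odd irises possible")
    elif rep.white_pattern == "spotting_bicolor":
        rep.iris = "non-blue"
        rep.notes.append("white spotting can produce blue or odd irises, "
                         "but this is less common; non-blue reported")
    if (rep.color_modifier in ("colorpoint", "albino")
            and rep.white_pattern in ("spotting_bicolor", "full_white")):
        rep.notes.append("colourpoint/albino combined with white pattern: "
                         "interaction not modelled, traits reported independently")
    return rep


_TRAIT_ORDER = ["base_color", "color_modifier", "dilution", "white_pattern",
                "tabby_pattern", "coat_length", "coat_texture", "iris"]


def explain(report: PhenotypeReport) -> str:
    """One deterministic line per trait citing locus, genotype rule and
    defaults, followed by any notes."""
    cited = {}
    for trait, locus, rule in report.justifications:
        cited.setdefault(trait, []).append(f"{locus}: {rule}")
    lines = []
    for trait in _TRAIT_ORDER:
        value = getattr(report, trait)
        if trait in cited:
            lines.append(f"{trait} = {value} [" + "; ".join(cited[trait]) + "]")
        else:
            lines.append(f"{trait} = {value} [default/assumed]")
    for note in report.notes:
        lines.append(f"note: {note}")
    if report.assumed_loci:
        lines.append("assumed hom_ref at: " + ", ".join(report.assumed_loci))
    return "\n".join(lines)
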