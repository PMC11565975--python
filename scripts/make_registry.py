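"""Regenerate the packaged headgroup registry TSV.

The 64 headgroups cover the conjugatable amine classes the query set
targets: proteinogenic amino acids, non-proteinogenic amino acids,
polyamines, biogenic amines/neurotransmitters, thyroid hormones and other
diagnostically relevant metabolites.  Diagnostic fragment m/z values are
computed, not experimental: the protonated free headgroup [head+H]+ (the
dominant headgroup ion after amide cleavage) plus one characteristic
neutral loss (water when the head carries oxygen, else ammonia).

Run from the repository root:  python scripts/make_registry.py
"""

from __future__ import annotations

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from nacyl.chem_core import (  # noqa: E402
    PROTON_MASS,
    FragmentSpec,
    Headgroup,
    monoisotopic_mass,
    parse_formula,
    write_registry,
)

H2O = 18.010565
NH3 = 17.026549

# name, formula (free amine), n primary acylation sites, equivalence group
HEADGROUPS: list[tuple[str, str, int, str]] = [
    # proteinogenic amino acids
    ("glycine", "C2H5NO2", 1, ""),
    ("alanine", "C3H7NO2", 1, "ala_iso"),
    ("serine", "C3H7NO3", 1, ""),
    ("cysteine", "C3H7NO2S", 1, ""),
    ("aspartic acid", "C4H7NO4", 1, ""),
    ("asparagine", "C4H8N2O3", 1, ""),
    ("threonine", "C4H9NO3", 1, ""),
    ("glutamic acid", "C5H9NO4", 1, ""),
    ("glutamine", "C5H10N2O3", 1, ""),
    ("proline", "C5H9NO2", 1, ""),
    ("valine", "C5H11NO2", 1, ""),
    ("methionine", "C5H11NO2S", 1, ""),
    ("lysine", "C6H14N2O2", 2, ""),
    ("leucine", "C6H13NO2", 1, "leu_iso"),
    ("isoleucine", "C6H13NO2", 1, "leu_iso"),
    ("histidine", "C6H9N3O2", 1, ""),
    ("arginine", "C6H14N4O2", 1, ""),
    ("phenylalanine", "C9H11NO2", 1, ""),
    ("tyrosine", "C9H11NO3", 1, ""),
    ("tryptophan", "C11H12N2O2", 1, ""),
    # non-proteinogenic amino acids and related acids
    ("sarcosine", "C3H7NO2", 1, "ala_iso"),
    ("beta-alanine", "C3H7NO2", 1, "ala_iso"),
    ("homoserine", "C4H9NO3", 1, ""),
    ("ornithine", "C5H12N2O2", 2, ""),
    ("citrulline", "C6H13N3O3", 1, ""),
    ("aminoadipic acid", "C6H11NO4", 1, ""),
    ("GABA", "C4H9NO2", 1, ""),
    ("2-aminobutyric acid", "C4H9NO2", 1, ""),
    ("5-aminovaleric acid", "C5H11NO2", 1, ""),
    ("homocysteine", "C4H9NO2S", 1, ""),
    ("selenomethionine", "C5H11NO2Se", 1, ""),
    ("3-methoxytyrosine", "C10H13NO4", 1, ""),
    # polyamines and small amines
    ("ethanolamine", "C2H7NO", 1, ""),
    ("1,3-diaminopropane", "C3H10N2", 2, ""),
    ("putrescine", "C4H12N2", 2, ""),
    ("cadaverine", "C5H14N2", 2, ""),
    ("spermidine", "C7H19N3", 2, ""),
    ("spermine", "C10H26N4", 2, ""),
    ("agmatine", "C5H14N4", 1, ""),
    ("taurine", "C2H7NO3S", 1, ""),
    # biogenic amines / neurotransmitters
    ("histamine", "C5H9N3", 1, ""),
    ("dopamine", "C8H11NO2", 1, ""),
    ("serotonin", "C10H12N2O", 1, ""),
    ("tyramine", "C8H11NO", 1, ""),
    ("tryptamine", "C10H12N2", 1, ""),
    ("2-phenethylamine", "C8H11N", 1, ""),
    ("octopamine", "C8H11NO2", 1, ""),
    ("norepinephrine", "C8H11NO3", 1, ""),
    ("epinephrine", "C9H13NO3", 1, ""),
    ("normetanephrine", "C9H13NO3", 1, ""),
    ("metanephrine", "C10H15NO3", 1, ""),
    ("5-methoxytryptamine", "C11H14N2O", 1, ""),
    # hormones, redox metabolites and other diagnostic amines
    ("kynurenine", "C10H12N2O3", 1, ""),
    ("glutathione", "C10H17N3O6S", 1, ""),
    ("thyroxine", "C15H11I4NO4", 1, ""),
    ("liothyronine", "C15H12I3NO4", 1, ""),
    ("3-iodothyronamine", "C14H14INO2", 1, ""),
    ("thyronamine", "C14H15NO2", 1, ""),
    ("anthranilic acid", "C7H7NO2", 1, ""),
    ("3-hydroxyanthranilic acid", "C7H7NO3", 1, ""),
    ("4-aminobenzoic acid", "C7H7NO2", 1, ""),
    ("glucosamine", "C6H13NO5", 1, ""),
    ("5-hydroxytryptophan", "C11H12N2O3", 1, ""),
    ("DOPA", "C9H11NO4", 1, ""),
]


def build() -> list[Headgroup]:
    heads = []
    for name, formula_text, n_sites, equiv in HEADGROUPS:
        formula = parse_formula(formula_text)
        mh = monoisotopic_mass(formula) + PROTON_MASS
        loss = H2O if formula.get("O", 0) >= 1 else NH3
        frags = (
            FragmentSpec(mz=mh, tolerance=0.02, min_relative_intensity=0.01),
            FragmentSpec(mz=mh - loss, tolerance=0.02, min_relative_intensity=0.01),
        )
        heads.append(
            Headgroup(
                name=name,
                formula=formula,
                diagnostic_fragments=frags,
                n_acylation_sites=n_sites,
                equivalence_group=equiv or None,
            )
        )
    return heads


if __name__ == "__main__":
    heads = build()
    assert len(heads) == 64, len(heads)
    out = Path(__file__).resolve().parents[1] / "src" / "nacyl" / "data"
    out.mkdir(parents=True, exist_ok=True)
    write_registry(heads, out / "headgroups_synthetic.tsv")
    print(f"wrote {len(heads)} headgroups to {out / 'headgroups_synthetic.tsv'}")
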