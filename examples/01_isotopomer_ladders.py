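"""From a chemical formula to a theoretical isotopomer ladder.

Computes the monoisotopic mass of dipalmitoyl phosphatidylcholine, forms
its formate-adduct anion, and expands the ion into the M+0…M+40 ladder a
fully ¹³C-labeled lipid could occupy.
"""

from isotrace import isotopomer_mz, monoisotopic_mass, parse_formula
from isotrace.chem import get_adduct, ion_mz

formula = parse_formula("C40H80NO8P")  # PC(16:0/16:0)
neutral = monoisotopic_mass(formula)
formate = get_adduct("+HCOO")
base = ion_mz(neutral, formate)

print(f"neutral monoisotopic mass : {neutral:.4f} Da")
print(f"[M+HCOO]-  ion m/z        : {base:.4f}  (rounds to {base:.2f})")
print(f"carbon count (ladder cap) : {formula.carbon_count}")
print()
print("first and last rungs of the ¹³C ladder (spacing 1.0033548378/z):")
for n in (0, 1, 2, 26, 39, 40):
    print(f"  M+{n:<2d} -> {isotopomer_mz(base, n):.4f}")
# The M+26 rung (804.6470) lies only 0.0716 Th above the M+0 of the
# co-eluting heavier lipid PC(16:0/18:1) formate ion (804.5755): the
# classic overlap the ppm gate must screen.
heavier = ion_mz(monoisotopic_mass(parse_formula("C42H82NO8P")), formate)
print(f"\nco-eluting PC(16:0/18:1) [M+HCOO]- : {heavier:.4f} "
      f"({abs(isotopomer_mz(base, 26) - heavier):.4f} Th from M+26)")
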