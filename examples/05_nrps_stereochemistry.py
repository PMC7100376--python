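"""Backbone stereochemistry from the ptc NRPS domain architecture.

Condensation-domain subtypes set each donor residue's configuration; the
TauD hydroxylase context converts the two Asp positions into threo/erythro
beta-OH-Asp diastereomers; the result is reconciled against the Marfey
residue inventory (the C_DCL expectation at position 8 is the one conflict).
"""

from siderokit import HydroxylaseContext, assign_hydroxylation, parse_domain_string, predict_backbone, reconcile
from siderokit.presets import MARFEY_INVENTORY, PTC_DOMAIN_STRING

arch = parse_domain_string(PTC_DOMAIN_STRING)
print(f"modules: 1 loading + {arch.n_extensions} extension")

ctx = HydroxylaseContext(standalone=(("PtcA", "3R"),), fused=((1, "3S"),))
pred = assign_hydroxylation(arch, predict_backbone(arch), ctx)

for r in pred.residues:
    extra = f"  [{r.hydroxylation}]" if r.hydroxylation else ""
    flag = "  <- conflict" if r.position in pred.conflict_positions else ""
    print(f"  {r.position}: {r.configuration:>7}-{r.substrate:<4} ({r.rule}){extra}{flag}")

report = reconcile(pred, MARFEY_INVENTORY)
print("reconciliation vs Marfey inventory:", report.verdict)
for note in report.notes:
    print("  note:", note)
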