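"""A tour of the cell-behaviour rule grammar.

Rules are single statements `id: A -> B [+ C], D`. Behavioural rules change a
cell's state or position with probability D (an expression over the
normalized context variables); environmental rules describe uptake or matrix
remodelling, tagged with the species they touch.
"""

from scaffoldsim import evaluate_probability, format_rule, parse_rule
from scaffoldsim.rules import RuleContext

types = {"P", "Q", "D"}
constants = {"a": 0.44, "c": 0.1}

statements = [
    "dup: P -> P + P, a * min(Glc, O2) / 24",   # duplication into a free neighbour
    "mv: P -> empty + P, 0.01",                  # random-walk migration
    "die: Q -> D, c * (1 - min(Glc, O2))",       # starvation-driven death
    "glc: P -> U, environment(Glc)",             # reference glucose uptake
    "stiffen: P -> U, environment(YM)",          # LOX matrix cross-linking
]

well_fed = RuleContext(TIME=0.1, TD=0, Glc=0.95, O2=1.0, AGE=0.2, TLD=0.1, YM=1.0)
starved = RuleContext(TIME=0.9, TD=0, Glc=0.05, O2=0.9, AGE=0.5, TLD=0.3, YM=1.2)

for line in statements:
    rule = parse_rule(line, cell_types=types, constants=constants)
    print(f"{format_rule(rule)}")
    if hasattr(rule, "probability_expr"):
        p_fed = evaluate_probability(rule, well_fed, constants)
        p_hungry = evaluate_probability(rule, starved, constants)
        print(f"    p(well-fed) = {p_fed:.4f}   p(starved) = {p_hungry:.4f}")
    else:
        print(f"    environmental: tag {rule.tag}, amount {rule.amount}")

print()
print("Probabilities are clamped to [0, 1]; 'U' resolves to the reference")
print("per-cell uptake of the tagged species (Glc 16.7e-12, O2 2.93e-15 g/cell/h).")
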