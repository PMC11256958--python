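"""POCP recovers a constructed shared-protein fraction.

Generates proteome pairs that share 0%, 50%, and 100% of their proteins
and shows the measured POCP tracking the construction, then repeats the
50%-shared pair with heavy point mutation to show the identity filter
removing diverged proteins from the conserved set.
"""

from pocp import SyntheticPairSpec, compare_pair, generate_pair

print("shared_fraction  expected_pocp  measured_pocp")
for f in (0.0, 0.5, 1.0):
    a, b, expected = generate_pair(
        SyntheticPairSpec(n_proteins=40, shared_fraction=f, seed=42)
    )
    measured = compare_pair(a, b).pocp_pct
    print(f"{f:>15.2f}  {expected:>13.2f}  {measured:>13.2f}")

a, b, _ = generate_pair(
    SyntheticPairSpec(n_proteins=40, shared_fraction=0.5, point_mutation_rate=0.7, seed=42)
)
mutated = compare_pair(a, b).pocp_pct
print(f"\n50% shared, 0.7 substitutions/site: measured POCP {mutated:.2f}")
print(
    "\nWith no mutation the measured POCP equals the constructed fraction;\n"
    "at 0.7 substitutions per site the shared proteins fall to ~30% identity,\n"
    "below the strict 40% filter, so conservation largely disappears."
)
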