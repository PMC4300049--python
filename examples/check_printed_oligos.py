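"""Verify the packaged bench-validated oligo sets.

Reconstructs the coding strands from the printed main chains, validates every
helper across its junction, and plans the assembly: the 276-nt set fits in
one tube, while the combined 34-oligo set needs the two printed tubes because
no helper spans the 540|541 boundary.
"""

from lcrgene import EnergyModel, load_fixture, plan_protocol, reconstruct
from lcrgene.assembly import plan_protocol_fragments

model = EnergyModel()

short = load_fixture("ubp4_prime")
dna, n = reconstruct(list(short.fragments))
proto = plan_protocol_fragments(list(short.fragments), model=model)
print(f"ubp4_prime: {len(short.fragments)} oligos reconstruct {n} nt; "
      f"verdict {proto.report.verdict}, {len(proto.tubes)} tube(s), S = {proto.S}")
print(f"  weakest designed junction melts at {proto.report.threshold:.1f} C")

a = load_fixture("ubp4_dprime_a")
b = load_fixture("ubp4_dprime_b")
combined = list(a.fragments) + list(b.fragments)
proto2 = plan_protocol_fragments(combined, model=model)
print(f"ubp4_dprime a+b: {len(combined)} oligos; verdict "
      f"{proto2.report.verdict}, {len(proto2.tubes)} tubes, S = {proto2.S}")
for pair, reason in proto2.conflicts:
    print(f"  conflict {pair[0]} / {pair[1]}: {reason}")
print("Each leaf tube runs one base protocol; merging the two products is a")
print("third base-protocol execution, hence S = 3 for the long gene.")
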