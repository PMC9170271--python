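"""Dirichlet opinions and entropy-based difficulty, on two hand-picked cases.

A classifier's pre-softmax outputs are rectified into evidence e, giving a
Dirichlet opinion alpha = e + 1 with expectation p = alpha / sum(alpha).
The Shannon entropy of p (bits) measures how committed the opinion is: a
confident residue yields a sharp opinion and low entropy, an ambiguous one
a flat opinion and high entropy — the signal that routes residues to the
easy or hard classifier.
"""

import mccm

for name, logits in [("confident residue", [13.10, 0.33, 0.21]),
                     ("ambiguous residue", [1.24, 0.82, 0.78])]:
    op = mccm.opinion_from_logits(logits)
    p = ", ".join(f"{v:.4f}" for v in op.expectation)
    alpha = ", ".join(f"{v:.2f}" for v in op.alpha)
    print(f"{name}: alpha=[{alpha}], strength S={op.strength:.2f}")
    print(f"  expectation p = [{p}]  entropy H = {op.entropy:.4f} bits")

loss = mccm.dirichlet_loss([1.0, 0.0, 0.0], mccm.opinion_from_logits([-1.0, -1.0, -1.0]))
print(f"\nevidential loss for a totally uninformed opinion vs truth class 1: {loss:.4f}")
print("(= 5/6: squared error of the uniform expectation plus its Dirichlet variance)")
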