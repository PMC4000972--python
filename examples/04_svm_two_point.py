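"""Fit the soft-margin SVM on the canonical two-point problem.

Points x = -1 (label -1) and x = +1 (label +1) admit a closed-form
hard-margin solution: dual coefficients alpha = (0.5, 0.5), weight w = 1,
bias b = 0, geometric margin 2/||w|| = 2.  The SMO solver recovers it.
"""

import numpy as np

from gaborgist import KernelSpec, TrainingSet, decision_function, predict, solve_dual

train = TrainingSet(np.array([[-1.0], [1.0]]), np.array([-1.0, 1.0]))
model = solve_dual(train, C=10.0, spec=KernelSpec("linear"))

print(f"alphas: {model.alphas}")
print(f"w = {model.weights[0]:.6f}, b = {model.bias:.2e}")
print(f"geometric margin 2/||w|| = {2 / np.linalg.norm(model.weights):.6f}")
for x in (-3.0, 0.0, 2.0):
    f = decision_function(model, np.array([x]))
    print(f"f({x:+.0f}) = {f:+.3f} -> predicted label {predict(model, np.array([x])):+d}")
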