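"""Privacy controls at the client-server boundary.

Three mechanisms: payload quantization to a fixed number of decimal digits
(trading precision for network latency), the disclosure guard rejecting
coefficient vectors with more nonzeros than the server has subjects, and
the shared-only policy keeping iNMF's cohort-specific factors on-server.
"""

import numpy as np

from fedmtl import (
    Case1Spec,
    PrivacyPolicy,
    create_session,
    disclosure_guard,
    fit_lasso,
    gen_case1,
    quantize,
)

print("quantize([3.14159, -0.005], digits=2) ->",
      quantize(np.array([3.14159, -0.005]), 2))

# fitting under coarse quantization: the solution moves, but only slightly
datasets, _ = gen_case1(Case1Spec(T=2, p=40, n_per_task=30, seed=5))
exact = fit_lasso(create_session(datasets), lam=0.3).model.W
coarse = fit_lasso(
    create_session(datasets, PrivacyPolicy(digits=3)), lam=0.3
).model.W
print(f"max |W_digits3 - W_exact| = {np.abs(coarse - exact).max():.2e} "
      "(payloads rounded to 3 decimals)")

# disclosure guard: a model with more nonzeros than subjects is rejected
dense = np.ones(40)
sparse = np.zeros(40)
sparse[:10] = 1.0
print("release 40-nonzero model from a 30-subject server:",
      "pass" if disclosure_guard(dense, 30) else "reject")
print("release 10-nonzero model from a 30-subject server:",
      "pass" if disclosure_guard(sparse, 30) else "reject")
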