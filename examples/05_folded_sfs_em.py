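"""Folded site-frequency spectrum from genotype likelihoods by EM.

Simulates genotypes from a known folded spectrum, degrades them to
5x-coverage genotype likelihoods, and compares the EM spectrum estimate
with naive maximum-likelihood genotype calling. The EM estimate is closer
to the truth in total-variation distance because it integrates over
genotype uncertainty instead of committing to a best call per sample.
"""

import numpy as np

from amtscan import diversity
from amtscan.synthetic_data import simulate_genotype_likelihoods

rng = np.random.default_rng(17)
n_samples, n_sites = 10, 500
n = 2 * n_samples

true_q = np.concatenate([[2.0], [1 / m for m in range(1, n // 2 + 1)]])
true_q /= true_q.sum()
counts = rng.choice(np.arange(n // 2 + 1), size=n_sites, p=true_q)
genotypes = np.zeros((n_sites, n_samples), dtype=np.int64)
for i, m in enumerate(counts):
    hap = np.zeros(n, dtype=int)
    hap[rng.choice(n, size=m, replace=False)] = 1
    genotypes[i] = hap[::2] + hap[1::2]

gl = simulate_genotype_likelihoods(genotypes, mean_depth=5, error_rate=0.01, seed=23)
em = diversity.em_folded_sfs(gl, max_iter=300)
em_q = np.concatenate([[em.n_sites_monomorphic], em.eta])

called = gl.argmax(axis=2)
naive_counts = np.minimum(called.sum(axis=1), n - called.sum(axis=1))
naive_q = np.bincount(naive_counts, minlength=n // 2 + 1) / n_sites
emp_q = np.bincount(counts, minlength=n // 2 + 1) / n_sites

tv = lambda a, b: 0.5 * np.abs(a - b).sum()
print("folded class:      ", " ".join(f"{m:>6d}" for m in range(n // 2 + 1)))
print("realised truth:    ", " ".join(f"{v:6.3f}" for v in emp_q))
print("EM estimate:       ", " ".join(f"{v:6.3f}" for v in em_q))
print("naive calling:     ", " ".join(f"{v:6.3f}" for v in naive_q))
print(f"\ntotal-variation distance to truth: EM {tv(em_q, emp_q):.4f} "
      f"vs naive {tv(naive_q, emp_q):.4f}")
print("Naive calling at 5x inflates intermediate classes (heterozygote"
      "\nmiscalls); the EM spectrum stays close to the sampled truth.")
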