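"""Fit per-gene transcription kinetics and recover latent cell time.

Generates one noiseless gene from known parameters, fits the two-state
model, and compares fitted gamma/beta and the latent time ordering with
the generator's truth.
"""

import numpy as np
from scipy.stats import spearmanr

from pachydyn import KineticGene, fit_gene_kinetics, kinetics_expected

rng = np.random.default_rng(1)
gene = KineticGene(
    "demo", alpha_on=20.0, beta=1.0, gamma=0.5, t_switch=0.35,
    gene_class="repression",
)
true_time = np.sort(rng.uniform(0.0, 1.0, 300))
u, s = kinetics_expected(gene, true_time)

fit = fit_gene_kinetics(u, s, gene_id="demo")
rho = spearmanr(fit.latent_time, true_time).statistic

print(f"true gamma/beta  : {gene.gamma / gene.beta:.3f}")
print(f"fitted gamma/beta: {fit.gamma / fit.beta:.3f}")
print(f"fit likelihood   : {fit.fit_likelihood:.4f}")
print(f"latent-vs-true time Spearman: {rho:.3f}")

# gamma/beta is the identifiable rate ratio (beta is the time gauge); a
# likelihood near 1 means the curve explains nearly all the signal, and
# the Spearman shows the per-cell latent times reproduce the ordering.
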