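"""Compare feature extractors on the toy image task.

Trains the statistics baseline, an unsupervised autoencoder, a BCE-trained
classifier encoder and a contrastive encoder on toy disc/blob images, then
measures 3-sigma OOD detection downstream of each.
"""

from spcdrift import feature_ranking_experiment

table = feature_ranking_experiment(seed=0)
print(table.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
# Reading the table: the supervised and contrastive encoders detect most OOD
# images at a matched 95% specificity; the image-statistics baseline is above
# chance but far behind; the autoencoder flags almost nothing while keeping
# near-perfect specificity - unsupervised reconstruction places OOD images at
# distances similar to ID ones, so they are hard to tell apart.
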