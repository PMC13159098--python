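# Example configuration for the biscale CLI.
#
# `biscale simulate --config config.yaml --seed 7 --out cohort/` reads the
# `synth` section; the training commands (`pretrain`, `finetune`) read the
# `train` section.  Any field left out keeps its default.

synth:
  n_patients: 40        # bulk slides (one slide per patient)
  patches_per_slide: 30
  n_spot_slides: 10     # spatial (Visium-style) slides
  spots_per_slide: 50
  n_genes: 20           # size of the target gene panel G
  embed_dim: 16         # patch-embedding dimensionality d
  latent_dim: 4         # latent morphology factors per patch/spot
  noise_sd: 0.0         # Gaussian noise on embeddings (0 = noiseless)
  # count_depth: 20000  # expected per-spot library size; omit for exact
  #                     # (noiseless) log-expression targets
  # overdispersion: 0.2 # negative-binomial dispersion; 0 = Poisson

train:
  max_epochs: 200
  lr: 2.0e-4            # pretraining learning rate (fine-tuning uses 2e-5)
  weight_decay: 5.0e-3
  batch_size: 1         # one patient-level sample per optimization step
  patience: 20          # epochs without improvement before stopping
  lam: 0.1              # local/global mixing weight; the spatial up-sampling
                        # factor is round(1/lam)
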