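# myth

Federated prototypical-part learning with interpretable bias auditing.

Clients train prototypical-part image classifiers on private shards; a server
averages learnable parameters under one of two sharing schemes (`gm`: all
parameters; `pm`: prototypes + final layer only, finished with a local
prototype push and final-layer refit). Each client can then compare the
most-activated patches of its *local* vs the *global* prototypes on its own
private test images — a large divergence flags hidden systematic bias (e.g. a
visual marker spuriously correlated with one client's positive class) without
any image ever leaving a client.

The network is implemented on NumPy (no GPU/framework dependency): a small
stride-2 CNN backbone, two 1x1 add-on conv layers (ReLU, then Sigmoid), a
prototype layer scoring latent patches by squared-L2 distance converted to
log similarity, global max pooling and a linear softmax head. Gradients are
hand-derived and covered by numeric grad-checks.

## Layout

| module | role |
|---|---|
| `myth.model_core` | network, loss, local training |
| `myth.fed_protocol` | client/server simulation, parameter averaging, schemes |
| `myth.projection_viz` | prototype push, activation upsampling, 95th-percentile boxes, overlays |
| `myth.bias_audit` | marker/drain bias injection, local-vs-global audit, client flagging |
| `myth.synthdata` | seeded synthetic image generator, IID partitioning, balancing, splits |
| `myth.metrics_eval` | sensitivity/specificity, balanced accuracy, multi-seed summaries |
| `myth.cli` | `myth` command line, manifest/checkpoint I/O |

## CLI

```bash
myth gen-data  --out data --seed 1 --n-clients 4 --bias-client 3
myth train     --manifest data/manifest.csv --mode local     --out ckpts --seed 1
myth train     --manifest data/manifest.csv --mode federated --scheme gm --out ckpts --seed 1
myth eval      --manifest data/manifest.csv --checkpoints ckpts/global_seed1.npz --out results.csv
myth visualize --manifest data/manifest.csv --checkpoint ckpts/local_c0_seed1.npz --client 0 --out viz
myth audit     --manifest data/manifest.csv \
               --local-ckpt ckpts/local_c0_seed1.npz --local-ckpt ckpts/local_c1_seed1.npz \
               --local-ckpt ckpts/local_c2_seed1.npz --local-ckpt ckpts/local_c3_seed1.npz \
               --global-ckpt ckpts/global_seed1.npz --out audit.json
```

`gen-data` accepts a YAML config with a `world:` block (image size, disease
feature, contrast, noise, per-class count).

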