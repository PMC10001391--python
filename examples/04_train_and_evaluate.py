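"""Overfit the miniature network on a handful of phantom slices, then score it.

Training uses the soft dice loss (squared-denominator form averaged over the
four classes), Adam, and the polynomial learning-rate decay
alpha0 * (1 - e/Ne)^0.9. Evaluation derives the three clinical regions
(whole tumor, tumor core, enhancing tumor) from the argmax labels and
reports DSC / IoU / HD95 / precision / recall / F1 / accuracy per region.
"""

import numpy as np

from brainseg import build_model, metrics, phantom, preprocess, tiny_config, training

cases = phantom.generate_dataset(6, seed=7)
pairs = [preprocess.preprocess_case(v, l, target=64) for v, l in cases]
train_pairs, val_pairs = pairs[:4], pairs[4:]

model = build_model(tiny_config(seed=1))
config = training.TrainConfig(alpha0=2e-2, epochs=50, batch_size=4, seed=0)
history = training.train(model, (train_pairs, val_pairs), config)

print(f"epochs run: {len(history.train_loss)}")
print(f"dice loss: first epoch {history.train_loss[0]:.3f} -> "
      f"last {history.train_loss[-1]:.3f}")
print(f"best checkpoint: epoch {history.best_epoch} "
      f"(validation dice {history.best_val_dice:.3f})")
print(f"learning rate decayed {history.learning_rates[0]:.2e} -> "
      f"{history.learning_rates[-1]:.2e}")

model.load_state(history.best_state)
summary = metrics.evaluate_split(model, val_pairs)
for region in metrics.REGIONS:
    row = summary[region]
    print(f"{region:>4}: DSC {row['dsc']:.3f}  IoU {row['iou']:.3f}  "
          f"HD95 {row['hd95']:.2f} mm  F1 {row['f1']:.3f}")
print("DSC/IoU near 1 and HD95 near 0 mean the phantom tumor compartments "
      "were recovered almost exactly on held-out slices.")
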