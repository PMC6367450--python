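"""The attention-augmented recurrent model (Ra-SCNN).

Shows the soft-attention mechanics — scores softmax to weights that sum to
one, uniform weights reduce to the sequence mean — and that one training
step sends gradient into the convolutional front-end (which is trained
jointly with the recurrent stage, never frozen).
"""

import numpy as np

from megdecode import RaSCNN, RaSCNNConfig, SCNNConfig, attention_apply, attention_weights
from megdecode.autodiff import Adam
from megdecode.training import cross_entropy

scores = np.array([np.log(2.0), 0.0])
alpha = attention_weights(scores)
print(f"softmax of [ln 2, 0] -> {alpha.round(4)}  (2/3, 1/3)")

features = np.array([[1.0], [3.0]])
print(f"attention-weighted feature with weights [0.25, 0.75]: "
      f"{attention_apply(features, np.array([0.25, 0.75])):.2f}  (1*0.25 + 3*0.75)")

front = SCNNConfig(spatial_layers=((6, 4),), temporal_filters=4,
                   temporal_kernel_taps=5, pool_width=4, activation="selu", seed=0)
model = RaSCNN(RaSCNNConfig(front_end=front, hidden_units=8, attention_layers=1,
                            n_classes=2, seed=0), T=40, C=6)
print(f"Ra-SCNN: {model.param_count()} parameters, "
      f"feature sequence length {model.seq_len} x {model.n_feat}")

rng = np.random.default_rng(0)
x = rng.normal(size=(8, 40, 6))
y = np.eye(2)[rng.integers(0, 2, 8)]
opt = Adam(model.parameters(), lr=1e-3)
loss = cross_entropy(model.forward(x, train=True), y)
loss.backward()
front_grad = max(float(np.abs(p.grad).max()) for p in model.front.parameters()
                 if p.grad is not None)
print(f"loss {float(loss.data):.4f}; largest front-end gradient magnitude {front_grad:.2e} "
      "(non-zero: the front-end trains jointly)")
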