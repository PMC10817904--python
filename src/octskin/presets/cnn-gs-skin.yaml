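# Lean skin-OCT patch classifier: 3x3 valid convolutions, filters 8/16/16,
# 2x2 stride-2 pooling with floor-rounded output sizes (55->53->26->24->12->10->5,
# flatten 400), FC1 32.  Total trainable parameters: 16,532.
input_size: 55
conv_kernels: [3, 3, 3]
conv_filters: [8, 16, 16]
conv_padding: [valid, valid, valid]
pool_kernels: [2, 2, 2]
pool_strides: [2, 2, 2]
pool_types: [max, avg, avg]
pool_rounding: [floor, floor, floor]
fc1_units: 32
dropout_rate: 0.1
n_outputs: 4
loss: categorical_crossentropy
learning_rate: 0.001
batch_size: 512
max_epochs: 50
patience: 5
seed: 0
name: cnn-gs-skin
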