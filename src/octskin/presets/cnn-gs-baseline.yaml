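# Baseline patch classifier: 5x5 valid convolutions, filters 32/32/64,
# pooling 2x2/3x3/3x3 stride 2 with ceil-rounded output sizes
# (55->51->26->22->11->7->3, flatten 576), FC1 64.
# Total trainable parameters: 114,916.
input_size: 55
conv_kernels: [5, 5, 5]
conv_filters: [32, 32, 64]
conv_padding: [valid, valid, valid]
pool_kernels: [2, 3, 3]
pool_strides: [2, 2, 2]
pool_types: [max, avg, avg]
pool_rounding: [ceil, ceil, ceil]
fc1_units: 64
dropout_rate: 0.1
n_outputs: 4
loss: categorical_crossentropy
learning_rate: 0.001
batch_size: 512
max_epochs: 50
patience: 5
seed: 0
name: cnn-gs-baseline
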