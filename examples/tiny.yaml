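model: {stem_channels: [2, 3], ms_out_channels: 4, gru_hidden: 3,
        gru_layers: 1, kan_hidden: 6}
train: {epochs: 12, batch_size: 16, learning_rate: 0.002}
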