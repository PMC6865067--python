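# Measured amplitude DSI of excitatory input to ON DS cells at 150 um/s
# (population mean +/- SD), for use as reference curves in rms_error.
condition,speed_um_s,dsi_mean,dsi_sd
control,150,0.35,0.08
cholinergic_block,150,0.26,0.05
cholinergic_gaba_block,150,0.21,0.05
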