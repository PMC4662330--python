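plot,accumulated_mm
control,198
drought,87
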