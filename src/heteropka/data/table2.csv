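compound,exp_drg,calc_drg,calc_de
pyridine,1601,1605,1648
pyrazine,1605,1605,1643
pyrimidine,1577,1579,1614
pyridazine,1565,1562,1601
imidazole,1433,1432,1466
succinimide,1414,1401,1436
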