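# Miniature synthetic stand-in for the EMA Designated Medical Events list
# (cardiac subset); not the official list.
Ventricular fibrillation
Torsade de pointes
Sudden cardiac death
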