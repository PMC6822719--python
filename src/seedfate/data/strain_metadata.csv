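strain_id,seed_source,genus_label,order_label
01A,D,Fusarium,Hypocreales
01B,D,Fusarium,Hypocreales
01C,D,Fusarium,Hypocreales
01D,D,Fusarium,Hypocreales
02A,V,Alternaria,Pleosporales
02B,D,Alternaria,Pleosporales
02C,V,Alternaria,Pleosporales
02D,V,Alternaria,Pleosporales
03A,D,Ascochyta,Pleosporales
03B,V&D,Ascochyta,Pleosporales
03C,V,Ascochyta,Pleosporales
04A,D,Fusarium,Hypocreales
04B,D,Fusarium,Hypocreales
05,V,Melanopsamma,Hypocreales
06,V,Aureobasidium,Dothideales
07,V,Fusarium,Hypocreales
08,V,Talaromyces,Eurotiales
09,V&D,Chaetomium,Sordariales
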