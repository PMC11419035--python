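gene_id	locus	segment	functional	paralog_canonical
IGKV1-16	IGK	V	true	IGKV1-16
IGKV1-33	IGK	V	true	IGKV1-33
IGKV1D-33	IGK	V	true	IGKV1-33
IGKV1-39	IGK	V	true	IGKV1-39
IGKV3-11	IGK	V	true	IGKV3-11
IGKV3-20	IGK	V	true	IGKV3-20
IGLV1-36	IGL	V	true	IGLV1-36
IGLV1-44	IGL	V	true	IGLV1-44
IGLV2-8	IGL	V	true	IGLV2-8
IGLV2-14	IGL	V	true	IGLV2-14
IGLV3-1	IGL	V	true	IGLV3-1
IGLV6-57	IGL	V	true	IGLV6-57
IGKJ1	IGK	J	true	IGKJ1
IGKJ2	IGK	J	true	IGKJ2
IGLJ2	IGL	J	true	IGLJ2
IGLJ3	IGL	J	true	IGLJ3
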