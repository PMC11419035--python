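>IGKV1-16
KKIKVFIICAMCIHVAVIQWWSASTVMQCEDTEENDVNIYHNGKHGWGWMKHTPPFQLTI
INTSADKYEQWGLWLMNINYTYLYTKCDHDCYYMSQMAKF
>IGKV1-33
TCLELVKHTELRASSQHFYKYGSIRRDSKYQLKGKMPDSRLVKKFLECYHVYAITDYCTT
CKKVVIRSRWEHLGGLPKYLSRRMNSEKPPVEKNEWWFPE
>IGKV1D-33
TCLELVKHTELRASSQHFYKYGSIRRDSKYQLKGKMPDSRLVKKFLECYHVYAITDYCTT
CKKVVIRSRWEHLGGLPKYLSRRMNSEKPPVEKNEWWFPE
>IGKV1-39
WPIMALHLVRDIIQMAWTYEIIPYWPASMRADRGNEHAHNCACETKTKRDTCGLYDFQIC
GQYPYTGNIKCLDFNTPFAETPNLEQNLQKMRKHEKARMN
>IGKV3-11
QEYNSDRDCMTLLEAPKCDVIPFEYCTNHHSMEVFKKIYHGRHIKTHYMCENYYASPFFV
DKQKMVQRYMAWKYHRCWPKQANVNQAAQGPAGMKWYIDV
>IGKV3-20
NNTFPMEPMQRTVGNDVYCDANITNSVKDQCVECHRLTWTWVMFNYPLHPMIKQWPNYFK
GTFWNYLCNSWSINRNNEKVFPDCIVCLHRLYEQYAWDDV
>IGLV1-36
MMIYGPSPSFLGYVMQAAADQTDKQWPLIVGAEIAYTLKLCGHARGYYHCQMQDMEHLIN
RSYNIRVYQYWFRIDYMVFFQLSFNLLVMDVKKYWSDSQV
>IGLV1-44
EYDIFSHLLMHFSRQPCNKMAIESYYRHMCARRFAGNLVGMPRMAWHVPMIFPHMRFCRP
DPLNGDRNQKPYTTPDPEQHIPNWNFKIVQTAFWFGAWWT
>IGLV2-8
PQRCAVRNKTATQSHSSPQYVYLGNSYLECCMWKHHVGHDYCMACFLIRAWLFFGEEFMT
MCLFFNVLESACDTKWNAYGEQGERFYRALESATWLWPGQ
>IGLV2-14
LHCQTNHWPKYAEDTTGLRQVWPCGEWLITHGCCDCTFSCPYVVWRDVVDESDDRTNRLN
YFENIFTCMVDTMTGVGVKKMLDLNDICDQDEFRNSHYCA
>IGLV3-1
YDFSIDWYAQYMLHSRNTVRIPMPQGVQNSNRIWRIHWKDFRGDYWKKKECKYYFYVNYY
TCYYIEHCHFTVIYLNDPEGSTNCHQIAGNKVWLTYYYPY
>IGLV6-57
SPGWQFCPRCFIFCFQDNSFGADVSKPAVPESQGWKWIMPKQPSTSWELCSQYAKMAWWS
ACIPYHPPYDEDMRYNIFKQTLWHDQEYEWFNFADHEHTW
>IGKJ1
CPLILMHKWR
>IGKJ2
FMKYENLYQK
>IGLJ2
TQPWRMQFIQ
>IGLJ3
TQPWRMQFIQ
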