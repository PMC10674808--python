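>ScV-LA-CP-standin synthetic stand-in capsid reference; conserved His at 154
SRVQHDNNWWTCWVGNRMSWYADQWHIMIDFVAIIFFPVQWNADIDHPHCMNPRHCQHSN
CGEQQDFYTEDDFFLIHFSILCRTSNRQQVSTKLSIKTLVLEKQYNCNYNNIHVKQQTPH
HKMYWRCNHHDKLRECTTQPKFPYAMDLMGYMYHHQPMTMWYKWAIEKKYERDCNQDFEG
TSHHFSHPEGFIQYYIPIKQVMFMYFEDQRRWWMKSPPYSIHFSGFQQTTQTDSNENDYP
YSATEWYDFITTIVCRRNDKHHDWRIFYCFMGYKGGPRNNDMIEPICKRCYWCVPDRNLP
QARLAPMCFMRDPELGLSFYCAGDKYCRMKNLGHWSMYHEQQVLEIFRMVPNKTLYRALL
GSQCVSIKGDICHTNADRYYYSMEHADTVGFFWIPERDQWRPEYVPMVPQSATVTQSRAW
GQEVRSAGHSYACPWITKGWAYVFDFGFPCWDWFPSGEWVATVLRFHPRGPRAQGGYNHM
APVSMFYPWFILVWSNWLYQDWENRHLGIPAQKQEQDPICPAHEHAEVLRMIGGQFNHSE
VHREGICWEFYAYFPYMSCDPIILCEVFEYRNLDPDWPSNCAPDWTWHMWRTDVYANIRF
THPYATRVACTDTQERFYLDEMQPCVSEHAAEAVKSNCCCFLMRILVTTRDVSWDGWTCY
KPVYTHYTNPNIRGHNGGQM
>ScV-LBC-CP-standin synthetic stand-in capsid reference; conserved His at 156
QVACYAEFRMQPEYQANVERLIALLKKRIEHHVGWHMWQMVHYGVKPPDVIDWTSEMSKQ
ADGEEDWNNNCREPALVHLSMMHEVFQFTLKHLGMCTPKWANIIDEKYNFHLATAMVVRP
SHPQMLCHYMQLFYSISFVGQHQNRCHDNGVHKERHQSSHRCVTHISARIWFCHNAPHNH
LGKATPMWSITKIHINVLGFVPYHSQETPDSRYYESLYNQPVSIEDAPAWRNGVGIAVYV
YFCMNDWRSNDHAFPGHPFNIHAHLSQEVCRDMVISCVFGYMYEWTNNQQKRSKKTQAEP
MKTTDENSGGKSHVLHFPMFKWVNDTPPHIFMMHQVFRLFPTLPPADEMFGFYHDQHLLA
FSKESVGWLHYLCTVMAEKVTTDNHQKYHKAMRHVDIDYVGCAPPMTCQFVGQGLGDCAQ
RQWLRFSFEDHCDESTKDCDHADCVLLKDWACCYGDSMAMMNRHDLSQPFAMMTHESADM
SHYGQAGATNLLKSFRFTYLSKTGFTPTCHHFQFFGYLCNATDLVLLQRKNYIWFMLMGI
GDYQDSLMECTKLCGQHMQWCKQEKMFTCCGHKKYMCPFHQCEEWNWMWDLFESWRHCWC
NLDWFSVHPREYCKLIFGFGGMFGGSVHLMCWFNRGQARTNFKTSQDPLEQEWAKDRPDR
SPWYQPRWLYNPLTTRRLRQPRQGNYGECQPIKHLYAQYTQPGSELNP
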