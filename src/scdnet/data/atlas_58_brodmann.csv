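id,ba,label,hemisphere,lobe,x,y,z
BA04_L,4,Precentral gyrus (primary motor),L,frontal,-33,-20,55
BA04_R,4,Precentral gyrus (primary motor),R,frontal,33,-20,55
BA06_L,6,Middle frontal gyrus (premotor),L,frontal,-28,0,50
BA06_R,6,Middle frontal gyrus (premotor),R,frontal,28,0,50
BA07_L,7,Precuneus / superior parietal lobule,L,parietal,-15,-65,50
BA07_R,7,Precuneus / superior parietal lobule,R,parietal,15,-65,50
BA08_L,8,Superior frontal gyrus,L,frontal,-22,25,45
BA08_R,8,Superior frontal gyrus,R,frontal,22,25,45
BA09_L,9,Dorsolateral prefrontal cortex,L,frontal,-30,35,30
BA09_R,9,Dorsolateral prefrontal cortex,R,frontal,30,35,30
BA10_L,10,Anterior prefrontal cortex,L,frontal,-22,55,10
BA10_R,10,Anterior prefrontal cortex,R,frontal,22,55,10
BA11_L,11,Orbitofrontal area,L,frontal,-20,40,-15
BA11_R,11,Orbitofrontal area,R,frontal,20,40,-15
BA13_L,13,Insular cortex,L,insular,-38,5,5
BA13_R,13,Insular cortex,R,insular,38,5,5
BA17_L,17,Primary visual cortex,L,occipital,-10,-85,2
BA17_R,17,Primary visual cortex,R,occipital,10,-85,2
BA18_L,18,Secondary visual cortex,L,occipital,-15,-90,10
BA18_R,18,Secondary visual cortex,R,occipital,15,-90,10
BA19_L,19,Middle occipital gyrus,L,occipital,-30,-80,20
BA19_R,19,Middle occipital gyrus,R,occipital,30,-80,20
BA20_L,20,Inferior temporal gyrus,L,temporal,-50,-25,-25
BA20_R,20,Inferior temporal gyrus,R,temporal,50,-25,-25
BA21_L,21,Middle temporal gyrus,L,temporal,-55,-20,-10
BA21_R,21,Middle temporal gyrus,R,temporal,55,-20,-10
BA22_L,22,Superior temporal gyrus,L,temporal,-55,-25,5
BA22_R,22,Superior temporal gyrus,R,temporal,55,-25,5
BA23_L,23,Posterior cingulate cortex,L,limbic,-5,-30,30
BA23_R,23,Posterior cingulate cortex,R,limbic,5,-30,30
BA24_L,24,Anterior cingulate cortex (ventral),L,limbic,-5,20,25
BA24_R,24,Anterior cingulate cortex (ventral),R,limbic,5,20,25
BA30_L,30,Retrosplenial cortex,L,parietal,-10,-50,10
BA30_R,30,Retrosplenial cortex,R,parietal,10,-50,10
BA31_L,31,Posterior cingulate cortex (dorsal),L,parietal,-8,-55,30
BA31_R,31,Posterior cingulate cortex (dorsal),R,parietal,8,-55,30
BA32_L,32,Anterior cingulate cortex (dorsal),L,limbic,-8,35,15
BA32_R,32,Anterior cingulate cortex (dorsal),R,limbic,8,35,15
BA37_L,37,Fusiform gyrus,L,temporal,-40,-55,-15
BA37_R,37,Fusiform gyrus,R,temporal,40,-55,-15
BA38_L,38,Temporopolar area,L,temporal,-40,15,-28
BA38_R,38,Temporopolar area,R,temporal,40,15,-28
BA39_L,39,Angular gyrus,L,parietal,-45,-60,30
BA39_R,39,Angular gyrus,R,parietal,45,-60,30
BA40_L,40,Supramarginal gyrus,L,parietal,-50,-40,40
BA40_R,40,Supramarginal gyrus,R,parietal,50,-40,40
BA41_L,41,Anterior transverse temporal gyrus,L,temporal,-45,-25,10
BA41_R,41,Anterior transverse temporal gyrus,R,temporal,45,-25,10
BA43_L,43,Subcentral area,L,insular,-55,-10,15
BA43_R,43,Subcentral area,R,insular,55,-10,15
BA44_L,44,Inferior frontal gyrus (pars opercularis),L,frontal,-50,12,15
BA44_R,44,Inferior frontal gyrus (pars opercularis),R,frontal,50,12,15
BA45_L,45,Inferior frontal gyrus (pars triangularis),L,frontal,-48,28,8
BA45_R,45,Inferior frontal gyrus (pars triangularis),R,frontal,48,28,8
BA46_L,46,Dorsolateral prefrontal cortex (mid),L,frontal,-42,38,18
BA46_R,46,Dorsolateral prefrontal cortex (mid),R,frontal,42,38,18
BA47_L,47,Inferior frontal gyrus (pars orbitalis),L,frontal,-38,28,-12
BA47_R,47,Inferior frontal gyrus (pars orbitalis),R,frontal,38,28,-12
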